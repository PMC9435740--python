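"""Presence/absence of transcript expression and Wagner-parsimony gain/loss.

A transcript is scored present in a species when its TPM exceeds the
presence threshold in all replicates (strict) or in at least two (lenient),
and absent when TPM is at or below the absence threshold in every replicate;
anything else is ambiguous and excluded from reconstruction. Gains and
losses are then placed on the fixed five-primate topology
((((human, chimpanzee), gorilla), orangutan), macaque) by Sankoff dynamic
programming over binary states with configurable gain/loss branch costs.
All optimal internal labelings are enumerated, so an event whose placement
differs between equally parsimonious scenarios (the classic macaque-versus-
great-apes case) is reported on every candidate branch with an explicit
ambiguity flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .models import ExpressionMatrix, ValidationError

DEFAULT_TREE = "((((H,C),G),O),M);"


@dataclass
class TreeNode:
    name: str
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self


class PhylogenyTree:
    """Rooted tree with named branches (one per non-root node)."""

    def __init__(self, newick: str = DEFAULT_TREE):
        dt = dendropy.Tree.get(data=newick, schema="newick")
        self.root = self._convert(dt.seed_node, None, counter=itertools.count())
        self.leaves = [n for n in self.root.postorder() if n.is_leaf]
        self.leaf_names = [n.name for n in self.leaves]
        self.nodes = list(self.root.postorder())

    def _convert(self, dnode, parent, counter):
        if dnode.is_leaf():
            name = dnode.taxon.label
        else:
            name = dnode.label or f"anc{next(counter)}"
        node = TreeNode(name=name, parent=parent)
        for ch in dnode.child_nodes():
            node.children.append(self._convert(ch, node, counter))
        return node

    @property
    def internal_nonroot(self):
        return [n for n in self.nodes if not n.is_leaf and n.parent is not None]

    def branch_name(self, node: TreeNode) -> str:
        """A branch is named by its child node; leaf branches by the leaf."""
        if node.is_leaf:
            return node.name
        return f"{node.name}({'+'.join(sorted(l.name for l in node.postorder() if l.is_leaf))})"


@dataclass
class ParsimonyResult:
    score: float
    events: list[dict]              # branch, type, ambiguous_direction
    root_states: set[int]
    n_optimal_labelings: int


def build_presence_matrix(
    expr: ExpressionMatrix,
    criterion: str = "strict",
    presence_threshold: float = 0.0,
    absence_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-transcript, per-species presence states.

    Returns a DataFrame indexed by transcript with one column per species
    holding 1, 0 or -1 (ambiguous), plus an ``ambiguous`` flag column.
    """
    if criterion not in ("strict", "lenient"):
        raise ValueError("criterion must be 'strict' or 'lenient'")
    species = expr.species_list
    cols = {}
    for sp in species:
        samples = expr.samples_for(sp)
        if criterion == "strict" and len(samples) < 2:
            raise ValidationError(f"species {sp} has <2 replicates (strict criterion)")
        sub = expr.tpm[samples]
        above = (sub > presence_threshold).sum(axis=1)
        below = (sub <= absence_threshold).sum(axis=1)
        n = len(samples)
        need = n if criterion == "strict" else 2
        state = np.full(len(sub), -1, dtype=int)
        state[above >= need] = 1
        state[below == n] = 0
        cols[sp] = state
    out = pd.DataFrame(cols, index=expr.tpm.index)
    out["ambiguous"] = (out[species] == -1).any(axis=1)
    return out


def sankoff(
    profile: dict[str, int],
    tree: PhylogenyTree,
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
) -> ParsimonyResult:
    """Minimum-cost gain/loss reconstruction of a binary leaf profile.

    Bottom-up Sankoff tables over states {0, 1}; the branch from a parent in
    state p to a child in state c costs ``gain_cost`` when (p, c) = (0, 1)
    and ``loss_cost`` when (1, 0). The root may take either state freely.
    All optimal labelings are recovered top-down; events not shared by every
    optimal labeling carry ``ambiguous_direction=True``.
    """
    for leaf in tree.leaf_names:
        if profile.get(leaf) not in (0, 1):
            raise ValidationError(f"leaf {leaf} has non-binary state {profile.get(leaf)}")

    def branch_cost(parent_state: int, child_state: int) -> float:
        if parent_state == child_state:
            return 0.0
        return gain_cost if child_state == 1 else loss_cost

    cost: dict[int, np.ndarray] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            c = np.array([np.inf, np.inf])
            c[profile[node.name]] = 0.0
        else:
            c = np.zeros(2)
            for s in (0, 1):
                for ch in node.children:
                    c[s] += min(
                        cost[id(ch)][cs] + branch_cost(s, cs) for cs in (0, 1)
                    )
        cost[id(node)] = c

    root_cost = cost[id(tree.root)]
    score = float(root_cost.min())

    # top-down enumeration of all optimal state assignments
    labelings: list[dict[int, int]] = []

    def expand(assignments: dict[int, int], pending: list[TreeNode]):
        if not pending:
            labelings.append(dict(assignments))
            return
        node, rest = pending[0], pending[1:]
        parent_state = assignments[id(node.parent)] if node.parent else None
        for s in (0, 1):
            if node.is_leaf and profile[node.name] != s:
                continue
            # optimality check: state s at node must achieve the parent's choice
            if node.parent is None:
                if root_cost[s] > score + 1e-9:
                    continue
            else:
                best = min(
                    cost[id(node)][cs] + branch_cost(parent_state, cs) for cs in (0, 1)
                )
                if cost[id(node)][s] + branch_cost(parent_state, s) > best + 1e-9:
                    continue
            assignments[id(node)] = s
            expand(assignments, rest)
            del assignments[id(node)]

    preorder = [n for n in reversed(list(tree.root.postorder()))]
    expand({}, preorder)

    event_sets = []
    root_states = set()
    for lab in labelings:
        root_states.add(lab[id(tree.root)])
        evs = set()
        for node in tree.nodes:
            if node.parent is None:
                continue
            p, c = lab[id(node.parent)], lab[id(node)]
            if p == 0 and c == 1:
                evs.add((tree.branch_name(node), "gain"))
            elif p == 1 and c == 0:
                evs.add((tree.branch_name(node), "loss"))
        event_sets.append(frozenset(evs))
    common = frozenset.intersection(*event_sets) if event_sets else frozenset()
    union = frozenset.union(*event_sets) if event_sets else frozenset()
    events = [
        {"branch": b, "type": ty, "ambiguous_direction": (b, ty) not in common}
        for b, ty in sorted(union)
    ]
    return ParsimonyResult(score, events, root_states, len(labelings))


def reconstruct_gain_loss(
    presence: pd.DataFrame,
    tree: PhylogenyTree | None = None,
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
) -> pd.DataFrame:
    """Run Sankoff reconstruction for every unambiguous presence profile.

    Returns one row per (transcript, event); transcripts without events
    (fully present or fully absent) contribute a row with event_type 'none'.
    Profiles are memoized: there are at most 2^5 distinct ones.
    """
    tree = tree or PhylogenyTree()
    species = tree.leaf_names
    cache: dict[tuple, ParsimonyResult] = {}
    rows = []
    usable = presence[~presence["ambiguous"]]
    for tid, row in usable[species].iterrows():
        key = tuple(int(v) for v in row)
        res = cache.get(key)
        if res is None:
            res = sankoff(dict(zip(species, key)), tree, gain_cost, loss_cost)
            cache[key] = res
        if not res.events:
            rows.append(
                {"transcript_id": tid, "score": res.score, "branch": "",
                 "event_type": "none", "ambiguous_direction": False}
            )
        for ev in res.events:
            rows.append(
                {"transcript_id": tid, "score": res.score, "branch": ev["branch"],
                 "event_type": ev["type"], "ambiguous_direction": ev["ambiguous_direction"]}
            )
    return pd.DataFrame(
        rows, columns=["transcript_id", "score", "branch", "event_type", "ambiguous_direction"]
    )


def call_species_specific(presence: pd.DataFrame, species: list[str] | None = None) -> dict[str, set[str]]:
    """Transcripts expressed in exactly one species and absent in the rest.

    Requires strict-criterion profiles with no ambiguous state.
    """
    if species is None:
        species = [c for c in presence.columns if c != "ambiguous"]
    out: dict[str, set[str]] = {sp: set() for sp in species}
    clean = presence[~presence["ambiguous"]]
    states = clean[species].to_numpy()
    ones = (states == 1).sum(axis=1)
    zeros = (states == 0).sum(axis=1)
    mask = (ones == 1) & (zeros == len(species) - 1)
    for tid, row in zip(clean.index[mask], states[mask]):
        focal = species[int(np.argmax(row == 1))]
        out[focal].add(tid)
    return out


def check_upregulation_confound(
    gene_tpm: pd.DataFrame,
    metadata: pd.DataFrame,
    focal_by_gene: dict[str, str],
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Gene-level focal-versus-rest up-regulation check.

    For each gene with a focal species, a Welch t-test on log2(TPM+1)
    (focal replicates vs all other samples), BH-adjusted across genes; a
    gene is flagged confounded when adjusted p < ``alpha`` and the focal
    log2 fold change is positive.
    """
    from scipy import stats as sps

    sp_of = dict(zip(metadata["sample_id"], metadata["species"]))
    rows = []
    for gene, focal in sorted(focal_by_gene.items()):
        vals = np.log2(gene_tpm.loc[gene].astype(float) + 1.0)
        focal_vals = np.array([v for s, v in vals.items() if sp_of[s] == focal])
        rest_vals = np.array([v for s, v in vals.items() if sp_of[s] != focal])
        lfc = focal_vals.mean() - rest_vals.mean()
        if np.allclose(focal_vals.var(), 0) and np.allclose(rest_vals.var(), 0):
            p = 1.0 if np.isclose(lfc, 0) else 0.0
        else:
            p = float(sps.ttest_ind(focal_vals, rest_vals, equal_var=False).pvalue)
        rows.append({"gene_id": gene, "focal_species": focal, "log2fc": lfc, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        from .stats import bh_adjust

        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["confounded"] = (out["p_adj"] < alpha) & (out["log2fc"] > 0)
    return out


def branch_event_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Counts of gains/losses per branch (ambiguous events counted separately)."""
    ev = events[events["event_type"] != "none"]
    out = (
        ev.groupby(["branch", "event_type", "ambiguous_direction"])
        .size()
        .reset_index(name="n_transcripts")
        .sort_values(["branch", "event_type"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out
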