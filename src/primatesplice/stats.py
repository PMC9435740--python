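"""Enrichment statistics, multiple-testing adjustment, rank tests, and the
splicing-evolution gene classes.

Gene sets are always tested against an explicit background; there is no
implicit genome-wide universe. The gene classes combine species-specific
transcript gains with DIU and DEU up-calls: human-specific, NHP-specific,
multi-species (independent up events in two or more species), other usage
changes, and fully conserved splicing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    test: str
    fold_change: float | None = None
    zero_cell: bool = False


def fisher_or_hypergeometric(
    query: set, annotation: set, background: set, mode: str = "fisher"
) -> EnrichmentResult:
    """Enrichment of ``annotation`` membership in ``query`` against ``background``.

    fisher mode: two-sided exact test (point-probability method) with
    OR = (a*d)/(b*c); a zero cell yields OR 0 or inf with ``zero_cell`` set
    (no continuity correction). hypergeometric mode: upper-tail
    over-representation p with fold change observed/expected.
    """
    if not query <= background:
        raise ValueError("query set must be a subset of the background")
    if not annotation:
        raise ValueError("annotation list is empty")
    ann = annotation & background
    a = len(query & ann)
    b = len(query - ann)
    c = len(ann - query)
    d = len(background) - a - b - c
    zero = 0 in (a, b, c, d)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    if mode == "fisher":
        p = float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        return EnrichmentResult(a, b, c, d, odds, p, "fisher", zero_cell=zero)
    if mode == "hypergeometric":
        M, n, N = len(background), len(ann), len(query)
        p = float(sps.hypergeom.sf(a - 1, M, n, N))
        expected = n * N / M
        fc = a / expected if expected > 0 else float("nan")
        return EnrichmentResult(a, b, c, d, odds, p, "hypergeometric", fold_change=fc, zero_cell=zero)
    raise ValueError(f"unknown mode {mode}")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through untouched."""
    p = np.asarray(p, float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if vals.size:
        out[ok] = sps.false_discovery_control(vals, method="bh")
    return out


def holm_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="holm")[1]
    return out


def grouped_rank_tests(
    values_by_class: dict[str, np.ndarray], method: str = "wilcoxon"
) -> pd.DataFrame:
    """All-pairs two-sided rank comparisons between value groups.

    ``wilcoxon``: Wilcoxon rank-sum per pair with Holm adjustment across
    pairs. ``dscf``: Dwass-Steel-Critchlow-Fligner — the pairwise standardized
    rank-sum statistic referred to the studentized range distribution.
    Classes with fewer than two values are skipped with a warning.
    """
    import warnings

    groups = {}
    for name, vals in values_by_class.items():
        vals = np.asarray(vals, float)
        if len(vals) < 2:
            warnings.warn(f"class {name} has <2 values; skipped")
            continue
        groups[name] = vals
    names = sorted(groups)
    k = len(names)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            x, y = groups[names[i]], groups[names[j]]
            if method == "wilcoxon":
                stat, p = sps.ranksums(x, y)
            elif method == "dscf":
                n1, n2 = len(x), len(y)
                ranks = sps.rankdata(np.concatenate([x, y]))
                w = ranks[:n1].sum()
                ew = n1 * (n1 + n2 + 1) / 2.0
                # tie-corrected variance of the rank sum
                _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
                n = n1 + n2
                tie = ((counts**3 - counts).sum()) / (n - 1) if n > 1 else 0.0
                var = n1 * n2 / 12.0 * ((n + 1) - tie / n)
                z = (w - ew) / np.sqrt(var) if var > 0 else 0.0
                stat = z * np.sqrt(2)
                p = float(sps.studentized_range.sf(abs(stat), k, np.inf)) if var > 0 else 1.0
            else:
                raise ValueError(f"unknown method {method}")
            direction = "greater" if np.median(x) > np.median(y) else "less"
            rows.append(
                {"class_a": names[i], "class_b": names[j], "statistic": float(stat),
                 "p": float(p), "direction": direction}
            )
    out = pd.DataFrame(rows, columns=["class_a", "class_b", "statistic", "p", "direction"])
    if method == "wilcoxon" and len(out):
        out["p_adj"] = holm_adjust(out["p"].to_numpy())
    elif len(out):
        out["p_adj"] = out["p"]
    return out


SPLICING_CLASSES = [
    "HUMAN_SPECIFIC_UP", "NHP_SPECIFIC_UP", "MULTI_SPECIES_UP", "OTHER_CHANGES", "CONSERVED",
]


def assign_splicing_classes(
    gain_calls: pd.DataFrame,
    diu_calls: pd.DataFrame,
    deu_calls: pd.DataFrame,
    universe: set[str],
    human_label: str = "H",
) -> pd.DataFrame:
    """Combine gain, DIU and DEU evidence into splicing-evolution gene classes.

    Inputs are tables with columns gene_id, species, direction (gain tables
    may omit direction; gains count as up). Precedence:
    MULTI_SPECIES_UP (up events in >=2 species) > HUMAN/NHP_SPECIFIC_UP >
    OTHER_CHANGES (any non-up or multi-directional evidence) > CONSERVED.
    Genes outside the universe are excluded with a warning.
    """
    import warnings

    up_by_gene: dict[str, set[str]] = {}
    other_by_gene: set[str] = set()

    def feed(tab: pd.DataFrame, default_up: bool):
        if tab is None or not len(tab):
            return
        for _, r in tab.iterrows():
            gene = r["gene_id"]
            if gene not in universe:
                warnings.warn(f"gene {gene} outside evaluated universe; excluded")
                continue
            direction = r.get("direction", "up" if default_up else "other")
            if direction == "up":
                up_by_gene.setdefault(gene, set()).add(r["species"])
            else:
                other_by_gene.add(gene)

    feed(gain_calls, default_up=True)
    feed(diu_calls, default_up=False)
    feed(deu_calls, default_up=False)

    rows = []
    for gene in sorted(universe):
        ups = up_by_gene.get(gene, set())
        if len(ups) >= 2:
            cls = "MULTI_SPECIES_UP"
        elif len(ups) == 1:
            cls = "HUMAN_SPECIFIC_UP" if human_label in ups else "NHP_SPECIFIC_UP"
        elif gene in other_by_gene:
            cls = "OTHER_CHANGES"
        else:
            cls = "CONSERVED"
        rows.append(
            {"gene_id": gene, "splicing_class": cls,
             "up_species": ",".join(sorted(ups))}
        )
    return pd.DataFrame(rows, columns=["gene_id", "splicing_class", "up_species"])


def read_gene_sets(path) -> dict[str, set[str]]:
    """GMT-like TSV: set name, description, then member genes."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets
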