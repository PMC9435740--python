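"""Independent brute-force oracles used to validate the implementation.

Everything here is written as literal, unoptimized enumeration of the
definitions, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------- parsimony

# fixed topology ((((H,C),G),O),M); internal nodes: n1=(H,C), n2=(n1,G),
# n3=(n2,O), root=(n3,M)
_LEAVES = ("H", "C", "G", "O", "M")


def brute_sankoff(profile: dict[str, int], gain_cost=1.0, loss_cost=1.0):
    """Exhaustive minimum over all 16 internal labelings (incl. root).

    Returns (score, set of optimal event-sets, set of optimal root states);
    an event is (branch_label, 'gain'|'loss') where internal branches are
    labeled by their clade leaf set.
    """

    def cost(p, c):
        if p == c:
            return 0.0
        return gain_cost if c == 1 else loss_cost

    best = math.inf
    optimal = []
    for n1 in (0, 1):
        for n2 in (0, 1):
            for n3 in (0, 1):
                for root in (0, 1):
                    total = (
                        cost(n1, profile["H"]) + cost(n1, profile["C"])
                        + cost(n2, n1) + cost(n2, profile["G"])
                        + cost(n3, n2) + cost(n3, profile["O"])
                        + cost(root, n3) + cost(root, profile["M"])
                    )
                    if total < best - 1e-12:
                        best = total
                        optimal = []
                    if abs(total - best) < 1e-12:
                        optimal.append((n1, n2, n3, root))
    event_sets, roots = set(), set()
    for n1, n2, n3, root in optimal:
        roots.add(root)
        states = {
            "H": profile["H"], "C": profile["C"], "G": profile["G"],
            "O": profile["O"], "M": profile["M"],
            "CH": n1, "CGH": n2, "CGHO": n3, "ROOT": root,
        }
        parent = {
            "H": "CH", "C": "CH", "CH": "CGH", "G": "CGH",
            "CGH": "CGHO", "O": "CGHO", "CGHO": "ROOT", "M": "ROOT",
        }
        evs = set()
        for child, par in parent.items():
            p, c = states[par], states[child]
            if (p, c) == (0, 1):
                evs.add((child, "gain"))
            elif (p, c) == (1, 0):
                evs.add((child, "loss"))
        event_sets.add(frozenset(evs))
    return best, event_sets, roots


def fitch(profile: dict[str, int]) -> int:
    """Fitch parsimony change count on the same fixed topology."""
    changes = 0

    def merge(a: set, b: set):
        nonlocal changes
        if a & b:
            return a & b
        changes += 1
        return a | b

    n1 = merge({profile["H"]}, {profile["C"]})
    n2 = merge(n1, {profile["G"]})
    n3 = merge(n2, {profile["O"]})
    merge(n3, {profile["M"]})
    return changes


# ---------------------------------------------------------------- AS events

def brute_as_events(transcripts) -> set[tuple]:
    """Literal enumeration of the event definitions over all isoform pairs.

    Returns a set of (class, intervals) keys, matching the package's
    deduplication key.
    """
    out = set()
    tx = list(transcripts)
    strand = tx[0].strand

    def introns(t):
        return [(t.exons[i][1], t.exons[i + 1][0]) for i in range(len(t.exons) - 1)]

    for a in tx:
        for b in tx:
            if a is b:
                continue
            # SE: internal exon of a spliced across by one junction of b
            for i in range(1, len(a.exons) - 1):
                p = a.exons[i - 1][1]
                q = a.exons[i + 1][0]
                if (p, q) in introns(b):
                    out.add(("SE", (a.exons[i],)))
            # RI: exon of a spans exactly one intron of b with its neighbors
            for j in range(len(b.exons) - 1):
                x = b.exons[j][0]
                y = b.exons[j + 1][1]
                intron = (b.exons[j][1], b.exons[j + 1][0])
                if (x, y) in a.exons:
                    out.add(("RI", (intron,)))
            # A5SS/A3SS: junction pairs sharing one boundary; the longer
            # junction's free boundary must land inside the exon adjacent to
            # the shorter junction (an SE configuration does not qualify)
            for ia in introns(a):
                for ib in introns(b):
                    if ia == ib:
                        continue
                    shared_end = ia[1] == ib[1] and ia[0] != ib[0]
                    shared_start = ia[0] == ib[0] and ia[1] != ib[1]
                    if not (shared_end or shared_start):
                        continue
                    if shared_end:
                        if ia[0] > ib[0]:
                            holder, short_i, long_i = a, ia, ib
                        else:
                            holder, short_i, long_i = b, ib, ia
                        flank = [e for e in holder.exons if e[1] == short_i[0]][0]
                        if not flank[0] < long_i[0]:
                            continue
                        cls = "A5SS" if strand == "+" else "A3SS"
                    else:
                        if ia[1] < ib[1]:
                            holder, short_i, long_i = a, ia, ib
                        else:
                            holder, short_i, long_i = b, ib, ia
                        flank = [e for e in holder.exons if e[0] == short_i[1]][0]
                        if not long_i[1] < flank[1]:
                            continue
                        cls = "A3SS" if strand == "+" else "A5SS"
                    out.add((cls, (min(ia, ib), max(ia, ib))))
    # MEX
    exon_sets = {t.transcript_id: set(t.exons) for t in tx}
    intron_sets = {t.transcript_id: set(introns(t)) for t in tx}
    contexts = {}
    for t in tx:
        for i in range(1, len(t.exons) - 1):
            ctx = (t.exons[i - 1][1], t.exons[i + 1][0])
            contexts.setdefault(ctx, set()).add(t.exons[i])
    for (p, q), exset in contexts.items():
        for e1 in exset:
            for e2 in exset:
                if e1 >= e2 or e1[1] > e2[0]:
                    continue
                direct_skip = any((p, q) in s for s in intron_sets.values())
                has_e1_only = any(e1 in s and e2 not in s for s in exon_sets.values())
                has_e2_only = any(e2 in s and e1 not in s for s in exon_sets.values())
                together = any(e1 in s and e2 in s for s in exon_sets.values())
                if has_e1_only and has_e2_only and not together and not direct_skip:
                    out.add(("MEX", (e1, e2)))
    return out


# ------------------------------------------------------------- exonic parts

def parts_per_base(transcripts):
    """Per-base membership oracle: runs of identical covering-transcript sets."""
    cover = {}
    for t in transcripts:
        for s, e in t.exons:
            for pos in range(s, e):
                cover.setdefault(pos, set()).add(t.transcript_id)
    if not cover:
        return []
    out = []
    positions = sorted(cover)
    run_start = positions[0]
    run_set = cover[positions[0]]
    prev = positions[0]
    for pos in positions[1:]:
        if pos == prev + 1 and cover[pos] == run_set:
            prev = pos
            continue
        out.append((run_start, prev + 1, frozenset(run_set)))
        run_start, run_set, prev = pos, cover[pos], pos
    out.append((run_start, prev + 1, frozenset(run_set)))
    return out


# --------------------------------------------------------------------- TMM

def tmm_straight_line(counts: np.ndarray, trim_m=0.3, trim_a=0.05):
    """Step-by-step TMM factors written independently (plain loops)."""
    counts = np.asarray(counts, float)
    n_genes, n_samples = counts.shape
    lib = counts.sum(axis=0)
    uqs = []
    for j in range(n_samples):
        col = counts[:, j] / lib[j]
        nz = col[col > 0]
        uqs.append(np.quantile(nz, 0.75))
    mean_uq = sum(uqs) / len(uqs)
    ref = min(range(n_samples), key=lambda j: abs(uqs[j] - mean_uq))
    factors = []
    for j in range(n_samples):
        if j == ref:
            factors.append(1.0)
            continue
        ms, as_, ws = [], [], []
        for g in range(n_genes):
            x, r = counts[g, j], counts[g, ref]
            if x > 0 and r > 0:
                m = math.log2((x / lib[j]) / (r / lib[ref]))
                a = 0.5 * math.log2((x / lib[j]) * (r / lib[ref]))
                w = 1.0 / (
                    (lib[j] - x) / (lib[j] * x) + (lib[ref] - r) / (lib[ref] * r)
                )
                ms.append(m)
                as_.append(a)
                ws.append(w)
        ms, as_, ws = np.array(ms), np.array(as_), np.array(ws)
        lo_m, hi_m = np.quantile(ms, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(as_, [trim_a, 1 - trim_a])
        keep = (ms >= lo_m) & (ms <= hi_m) & (as_ >= lo_a) & (as_ <= hi_a)
        if not keep.any():
            factors.append(1.0)
            continue
        factors.append(2 ** (float(np.sum(ws[keep] * ms[keep]) / np.sum(ws[keep]))))
    f = np.array(factors)
    return f / math.exp(np.mean(np.log(f)))


# --------------------------------------------------------------- statistics

def fisher_two_sided(a, b, c, d) -> float:
    """Two-sided Fisher p by hypergeometric point-probability summation,
    with exact integer combinatorics."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = math.comb(n, col1)

    def prob(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > n - row1:
            return 0.0
        return math.comb(row1, x) * math.comb(n - row1, col1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):    # standard relative tolerance for ties
            total += px
    return min(total, 1.0)


def bh_direct(p):
    """Direct BH step-up: sorted p * m / rank with trailing cumulative min."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = p[i] * m / (rank_idx + 1)
        running = min(running, val)
        adj[i] = running
    return adj


# ---------------------------------------------------------------- digestion

def brute_digest(protein, missed_max=2, len_min=7, len_max=40):
    """All substrings flanked by legal tryptic boundaries with at most
    ``missed_max`` internal cleavage sites."""
    n = len(protein)
    is_site = [
        protein[i] in "KR" and (i + 1 >= n or protein[i + 1] != "P")
        for i in range(n)
    ]
    out = set()
    for s in range(n):
        left_ok = s == 0 or is_site[s - 1]
        if not left_ok:
            continue
        for e in range(s + 1, n + 1):
            right_ok = e == n or is_site[e - 1]
            if not right_ok:
                continue
            internal = sum(is_site[s:e - 1])
            if internal <= missed_max and len_min <= e - s <= len_max:
                out.add((protein[s:e], internal))
    return out


# ------------------------------------------------------------- random genes

def random_toy_gene(rng: np.random.Generator, gene_id="g", n_transcripts=None):
    """A random gene: segment skeleton plus per-transcript subset/boundary
    edits, yielding SE/RI/A5SS/A3SS/MEX-rich isoform sets."""
    from primatesplice.models import TranscriptModel

    n_seg = int(rng.integers(4, 8))
    strand = "+" if rng.random() < 0.5 else "-"
    segs = []
    pos = int(rng.integers(0, 50))
    for _ in range(n_seg):
        length = int(rng.integers(20, 80))
        segs.append((pos, pos + length))
        pos += length + int(rng.integers(20, 60))
    n_tx = n_transcripts or int(rng.integers(2, 6))
    transcripts = []
    for k in range(n_tx):
        keep = sorted(rng.choice(n_seg, size=int(rng.integers(2, n_seg + 1)), replace=False))
        exons = [list(segs[i]) for i in keep]
        # merge an adjacent segment pair into one exon (retained intron)
        if len(exons) >= 2 and rng.random() < 0.3:
            i = int(rng.integers(0, len(exons) - 1))
            if exons[i][1] < exons[i + 1][0]:
                exons[i][1] = exons[i + 1][1]
                del exons[i + 1]
        # shift an internal boundary (alternative splice site)
        if len(exons) >= 2 and rng.random() < 0.5:
            i = int(rng.integers(0, len(exons)))
            shift = int(rng.integers(4, 15))
            if i + 1 < len(exons) and exons[i + 1][0] - (exons[i][1] + shift) >= 4:
                exons[i][1] += shift
            elif i > 0 and (exons[i][0] - shift) - exons[i - 1][1] >= 4:
                exons[i][0] -= shift
        transcripts.append(
            TranscriptModel(f"{gene_id}_t{k}", gene_id, "S", "chr1", strand,
                            tuple(tuple(e) for e in exons))
        )
    return transcripts
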