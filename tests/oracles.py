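"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import numpy as np

from snpdiv.io_formats import MISSING


def naive_upgma_newick(ids: list[str], d: np.ndarray) -> str:
    """O(n^3) UPGMA with the lexicographic tie-break, built on plain lists
    and string assembly, independent of the package implementation."""
    clusters: list[tuple[tuple[str, ...], str, float, int]] = [
        ((name,), name, 0.0, 1) for name in ids
    ]  # (sorted members, newick fragment, height, size)
    dist = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            key = frozenset({clusters[i][0], clusters[j][0]})
            dist[key] = float(d[i, j])

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = sorted([clusters[i][0], clusters[j][0]])
                val = dist[frozenset({clusters[i][0], clusters[j][0]})]
                cand = (val, (a, b))
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        (_val, _key), i, j = best
        ci, cj = clusters[i], clusters[j]
        a, b = sorted([ci, cj], key=lambda c: c[0])
        height = _val / 2.0
        frag = (
            f"({a[1]}:{height - a[2]:.12g},{b[1]}:{height - b[2]:.12g})"
        )
        members = tuple(sorted(ci[0] + cj[0]))
        size = ci[3] + cj[3]
        merged = (members, frag, height, size)
        rest = [c for k, c in enumerate(clusters) if k not in (i, j)]
        for other in rest:
            da = dist.pop(frozenset({ci[0], other[0]}))
            db = dist.pop(frozenset({cj[0], other[0]}))
            dist[frozenset({members, other[0]})] = (ci[3] * da + cj[3] * db) / size
        dist.pop(frozenset({ci[0], cj[0]}))
        clusters = rest + [merged]

    return clusters[0][1] + ";\n"


def brute_force_allele_sharing(dosage: np.ndarray) -> np.ndarray:
    """Double-loop per-locus tally of the allele-sharing distance."""
    n, l = dosage.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            total, count = 0.0, 0
            for locus in range(l):
                a, b = dosage[i, locus], dosage[j, locus]
                if a == MISSING or b == MISSING:
                    continue
                total += abs(int(a) - int(b)) / 2.0
                count += 1
            out[i, j] = total / count if count else np.nan
    np.fill_diagonal(out, 0.0)
    return out


def brute_force_gamete_ss(gam: np.ndarray, n_loci: int, groups: list[list[int]]):
    """Sum-over-pairs SS partition oracle on allele-copy rows.

    ``groups`` lists gamete indices per population; returns
    (ss_total, ss_among_pops, ss_among_indiv, ss_within_indiv) with
    individuals = consecutive gamete pairs (2i, 2i+1).
    """

    def d2(u, v):
        present = ~(np.isnan(gam[u]) | np.isnan(gam[v]))
        comp = present.sum()
        return ((gam[u][present] - gam[v][present]) ** 2).sum() * n_loci / comp

    def ss(members):
        total = 0.0
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                total += d2(members[x], members[y])
        return total / len(members)

    everyone = [g for grp in groups for g in grp]
    ss_total = ss(everyone)
    ss_wp = sum(ss(grp) for grp in groups)
    individuals = sorted({g // 2 for g in everyone})
    ss_wi = sum(ss([2 * i, 2 * i + 1]) for i in individuals)
    return ss_total, ss_total - ss_wp, ss_wp - ss_wi, ss_wi
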