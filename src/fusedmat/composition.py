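"""Base-composition and codon-usage diagnostics for the MAT region.

A region of long-term recombination suppression accumulates AT-biased
mutations, depressing GC content relative to the genomic background (here
58-63% GC) and shifting synonymous codon choice away from GC-rich codons.
These diagnostics tile GC over 2-kb windows, compute per-CDS GC, build RSCU
(relative synonymous codon usage) tables, and compare region vs genome with
a rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._genetics import CODON_AA, SENSE_CODONS, STOP_CODONS
from .io import Annotation, SequenceSet
from .synteny import WindowTrack

_GC = frozenset("GC")
_ACGT = frozenset("ACGT")


def gc_fraction(seq: str) -> Optional[float]:
    """GC / (A+C+G+T); ambiguity codes excluded. None when no unambiguous
    bases are present."""
    counted = sum(1 for c in seq if c in _ACGT)
    if counted == 0:
        return None
    return sum(1 for c in seq if c in _GC) / counted


def gc_windows(seq: str, window: int = 2000) -> WindowTrack:
    """GC percentage in non-overlapping tiled windows (final partial window
    emitted and flagged). Coverage-weighted mean of window values equals the
    whole-sequence GC exactly (weights = unambiguous bases per window)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    track = WindowTrack(window_size=window)
    for s in range(0, len(seq), window):
        e = min(s + window, len(seq))
        frac = gc_fraction(seq[s:e])
        track.windows.append(((s, e), 100.0 * frac if frac is not None else float("nan")))
    track.partial_final = len(seq) % window != 0
    return track


def cds_gc(annotation: Annotation, assembly: SequenceSet) -> dict:
    """Per-gene GC percentage of the concatenated CDS (strand-independent),
    with the mean over genes reported alongside."""
    table: dict[str, float] = {}
    skipped: list[str] = []
    for gene in annotation:
        seq = gene.cds_sequence(assembly)
        if not seq:
            skipped.append(gene.gene_id)
            continue
        frac = gc_fraction(seq)
        if frac is None:
            skipped.append(gene.gene_id)
            continue
        table[gene.gene_id] = 100.0 * frac
    mean = float(np.mean(list(table.values()))) if table else float("nan")
    return {"per_gene": table, "genome_mean": mean, "skipped": skipped}


@dataclass
class RSCUTable:
    """Observed codon counts and RSCU values, grouped by synonymous family.
    RSCU = observed count / mean count within the codon's family; families
    with zero observations are absent. Single-codon families (Met, Trp) have
    RSCU 1 by convention when observed."""

    counts: dict[str, int] = field(default_factory=dict)
    rscu: dict[str, float] = field(default_factory=dict)
    family_size: dict[str, int] = field(default_factory=dict)

    def gc3_mean_rscu(self) -> Optional[float]:
        """Mean RSCU over codons from multi-codon families ending in G or C."""
        vals = [v for c, v in self.rscu.items()
                if self.family_size[CODON_AA[c]] > 1 and c[2] in "GC"]
        return float(np.mean(vals)) if vals else None


def rscu(cds_set: Sequence[str]) -> RSCUTable:
    """Pooled RSCU table over a set of in-frame coding sequences (terminal
    stop codons trimmed; internal stops are an error)."""
    counts: dict[str, int] = {c: 0 for c in SENSE_CODONS}
    for k, cds in enumerate(cds_set):
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS #{k}: length not divisible by 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        for pos, codon in enumerate(codons):
            if codon in STOP_CODONS:
                raise ValueError(f"CDS #{k}: internal stop codon at {pos}")
            if codon in counts:
                counts[codon] += 1
    families: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        families.setdefault(CODON_AA[codon], []).append(codon)
    out = RSCUTable()
    for aa, codons in families.items():
        observed = sum(counts[c] for c in codons)
        if observed == 0:
            continue  # unobserved family: absent, not zero-divided
        mean = observed / len(codons)
        for c in codons:
            out.counts[c] = counts[c]
            out.rscu[c] = counts[c] / mean
        out.family_size[aa] = len(codons)
    out.counts = {c: out.counts[c] for c in out.rscu}
    return out


# ---------------------------------------------------------------------------
# Rank-sum (Mann-Whitney U) test


@dataclass
class RankSumResult:
    U: float
    n1: int
    n2: int
    p: float
    method: str  # "exact" | "normal-approximation"
    degenerate: bool = False


def _exact_rank_sum_p(ranks2: np.ndarray, n1: int, u_obs2: float,
                      alternative: str) -> float:
    """Exact one-sided p by dynamic programming over the permutation null of
    the rank-sum, with midranks (ranks doubled to integers)."""
    total = len(ranks2)
    max_sum = int(ranks2.sum())
    # table[k] = vector of counts over achievable doubled rank-sums for size-k subsets
    table = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(min(n1, total) - 1, -1, -1):
            row = table[k]
            nz = np.nonzero(row)[0]
            if len(nz) == 0:
                continue
            table[k + 1, nz + r] += row[nz]
    counts = table[n1]
    sums = np.arange(max_sum + 1)
    # doubled U = doubled rank-sum - 2 * n1(n1+1)/2
    u_all2 = sums - n1 * (n1 + 1)
    totals = counts.sum()
    if alternative == "less":
        mass = counts[u_all2 <= u_obs2].sum()
    else:
        mass = counts[u_all2 >= u_obs2].sum()
    return float(mass / totals)


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  alternative: str = "less") -> RankSumResult:
    """One-sided Mann-Whitney U with midranks for ties. The null distribution
    is exact (enumerated by dynamic programming) when n1*n2 <= 400, otherwise
    a normal approximation with continuity and tie correction is used."""
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per sample")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if np.all(combined == combined[0]):
        return RankSumResult(u, n1, n2, 1.0, "exact", degenerate=True)
    if n1 * n2 <= 400:
        ranks2 = np.round(ranks * 2).astype(int)
        p = _exact_rank_sum_p(ranks2, n1, 2 * u, alternative)
        return RankSumResult(u, n1, n2, p, "exact")
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return RankSumResult(float(res.statistic), n1, n2, float(res.pvalue),
                         "normal-approximation")
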