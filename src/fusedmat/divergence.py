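"""Codon-aware synonymous/nonsynonymous divergence and allele-similarity tests.

dS and dN are estimated by Nei-Gojobori (1986) counting with Jukes-Cantor
correction: per-codon synonymous site fractions are the fraction of one-step
mutations per position that preserve the encoded amino acid (mutations to
stop codons counted nonsynonymous); substitution differences between a codon
pair are averaged over all orderings of the differing positions, excluding
orderings that pass through a stop codon (if every ordering does, all are
used with stop-entering steps counted nonsynonymous). Standard errors come
from a seeded codon-resampling bootstrap.

The module also provides the three-strain closest-pair similarity call (which
allele pair of a gene is most similar), the between- vs within-mating-type
dS comparison by one-sided Student's t-test, and the breakpoint-vs-interior
("suspension bridge") divergence contrast.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._genetics import CODON_AA, CODON_INDEX, SENSE_CODONS, STOP_CODONS, BASES
from .align import NT_SCHEME, PROTEIN_SCHEME, ScoringScheme, align_global, local_score_nt
from .synteny import SyntenyBlocks, WindowTrack


# ---------------------------------------------------------------------------
# NG86 tables


@lru_cache(maxsize=1)
def _site_fractions() -> np.ndarray:
    """Synonymous site fraction per sense codon (changes to stops count as
    nonsynonymous)."""
    s = np.zeros(len(SENSE_CODONS))
    for idx, codon in enumerate(SENSE_CODONS):
        aa = CODON_AA[codon]
        total = 0.0
        for pos in range(3):
            for base in BASES:
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1:]
                if mutant not in STOP_CODONS and CODON_AA[mutant] == aa:
                    total += 1.0
        s[idx] = total / 3.0
    return s


def _pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over mutational
    pathways between two sense codons."""
    diff_positions = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order, allow_stops):
        current = codon_a
        sd = nd = 0.0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS or current in STOP_CODONS:
                if not allow_stops and nxt != codon_b:
                    return None
                nd += 1.0
            elif CODON_AA[current] == CODON_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd

    paths = []
    for order in itertools.permutations(diff_positions):
        res = walk(order, allow_stops=False)
        if res is not None:
            paths.append(res)
    if not paths:  # every ordering passes through a stop codon
        paths = [walk(order, allow_stops=True)
                 for order in itertools.permutations(diff_positions)]
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd


@lru_cache(maxsize=1)
def _difference_tables() -> tuple[np.ndarray, np.ndarray]:
    n = len(SENSE_CODONS)
    sd = np.zeros((n, n))
    nd = np.zeros((n, n))
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i <= j:
                sd[i, j], nd[i, j] = _pair_differences(a, b)
                sd[j, i], nd[j, i] = sd[i, j], nd[i, j]
    return sd, nd


def ng86_counts(codon_a: str, codon_b: str) -> tuple[float, float, float, float]:
    """(synonymous site fraction of a, of b, Sd, Nd) for one codon pair."""
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        raise ValueError("stop codon passed to ng86_counts")
    if codon_a not in CODON_INDEX or codon_b not in CODON_INDEX:
        raise ValueError(f"not a sense codon: {codon_a!r}/{codon_b!r}")
    s = _site_fractions()
    sd_t, nd_t = _difference_tables()
    i, j = CODON_INDEX[codon_a], CODON_INDEX[codon_b]
    return float(s[i]), float(s[j]), float(sd_t[i, j]), float(nd_t[i, j])


# ---------------------------------------------------------------------------
# Codon alignment (protein-guided)


@dataclass
class CodonAlignment:
    pairs: list[tuple[str, str]]
    n_dropped_gap: int

    @property
    def n_codons(self) -> int:
        return len(self.pairs)


def _codons(cds: str, name: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS {name}: length {len(cds)} not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]  # trim terminal stop
    for k, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"CDS {name}: internal stop codon at codon {k}")
    return codons


def codon_align(cds_a: str, cds_b: str,
                scheme: ScoringScheme = PROTEIN_SCHEME) -> CodonAlignment:
    """Align two in-frame CDS at the protein level and back-translate onto
    codons; codon pairs containing gaps or ambiguity codes are dropped and
    counted."""
    codons_a = _codons(cds_a.upper(), "a")
    codons_b = _codons(cds_b.upper(), "b")
    pep_a = "".join(CODON_AA.get(c, "X") for c in codons_a)
    pep_b = "".join(CODON_AA.get(c, "X") for c in codons_b)
    aln = align_global(pep_a, pep_b, scheme)
    pairs: list[tuple[str, str]] = []
    dropped = 0
    i = j = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            ca, cb = codons_a[i], codons_b[j]
            if ca in CODON_INDEX and cb in CODON_INDEX:
                pairs.append((ca, cb))
            else:
                dropped += 1  # ambiguity codes
        else:
            dropped += 1
        if x != "-":
            i += 1
        if y != "-":
            j += 1
    return CodonAlignment(pairs, dropped)


# ---------------------------------------------------------------------------
# dS / dN estimation


@dataclass
class DsEstimate:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: Optional[float]
    dN: Optional[float]
    SE_dS: Optional[float]
    SE_dN: Optional[float]
    status: str  # "ok" | "undefined"


def jc_correct(p: float) -> Optional[float]:
    """Jukes-Cantor multiple-hit correction; None when 1 - 4p/3 <= 0."""
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return None
    return -0.75 * float(np.log(arg))


def estimate_ds(aln: CodonAlignment, bootstrap_B: int = 1000,
                seed: int = 0, min_codons: int = 10) -> DsEstimate:
    """NG86 dS/dN with JC correction over a codon alignment.

    An undefined dS (proportion of synonymous differences at or beyond the
    JC saturation boundary pS >= 3/4) is reported with status "undefined" —
    printed as "Un" in tables. SE is a codon-resampling bootstrap with
    ``bootstrap_B`` replicates (0 disables); the SE is withheld when more
    than 10% of replicates are undefined.
    """
    n = aln.n_codons
    if n < min_codons:
        raise ValueError(f"alignment has {n} codons; floor is {min_codons}")
    s_frac = _site_fractions()
    sd_t, nd_t = _difference_tables()
    ia = np.array([CODON_INDEX[a] for a, _ in aln.pairs])
    ib = np.array([CODON_INDEX[b] for _, b in aln.pairs])
    per_s_sites = (s_frac[ia] + s_frac[ib]) / 2.0
    per_sd = sd_t[ia, ib]
    per_nd = nd_t[ia, ib]

    def summarize(weights: Optional[np.ndarray] = None):
        if weights is None:
            S = per_s_sites.sum()
            Sd = per_sd.sum()
            Nd = per_nd.sum()
            total = 3.0 * n
        else:
            S = weights @ per_s_sites
            Sd = weights @ per_sd
            Nd = weights @ per_nd
            total = 3.0 * weights.sum()
        N = total - S
        pS = Sd / S if S > 0 else 0.0
        pN = Nd / N if N > 0 else 0.0
        return S, N, Sd, Nd, pS, pN

    S, N, Sd, Nd, pS, pN = summarize()
    dS = jc_correct(pS)
    dN = jc_correct(pN)
    se_ds = se_dn = None
    if bootstrap_B > 0:
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(n, np.full(n, 1.0 / n), size=bootstrap_B)
        Sb = counts @ per_s_sites
        Nb = 3.0 * n - Sb
        with np.errstate(divide="ignore", invalid="ignore"):
            pSb = np.where(Sb > 0, (counts @ per_sd) / Sb, 0.0)
            pNb = np.where(Nb > 0, (counts @ per_nd) / Nb, 0.0)
            argS = 1.0 - (4.0 / 3.0) * pSb
            argN = 1.0 - (4.0 / 3.0) * pNb
            dSb = np.where(argS > 0, -0.75 * np.log(np.where(argS > 0, argS, 1.0)),
                           np.nan)
            dNb = np.where(argN > 0, -0.75 * np.log(np.where(argN > 0, argN, 1.0)),
                           np.nan)
        if np.isnan(dSb).mean() <= 0.10:
            se_ds = float(np.nanstd(dSb, ddof=1))
        if np.isnan(dNb).mean() <= 0.10:
            se_dn = float(np.nanstd(dNb, ddof=1))
    return DsEstimate(
        S_sites=float(S), N_sites=float(N), Sd=float(Sd), Nd=float(Nd),
        pS=float(pS), pN=float(pN), dS=dS, dN=dN,
        SE_dS=se_ds, SE_dN=se_dn,
        status="ok" if dS is not None else "undefined",
    )


def ds_between_cds(cds_a: str, cds_b: str, bootstrap_B: int = 0,
                   seed: int = 0) -> DsEstimate:
    """Convenience: protein-guided codon alignment followed by estimate_ds."""
    return estimate_ds(codon_align(cds_a, cds_b), bootstrap_B=bootstrap_B,
                       seed=seed)


# ---------------------------------------------------------------------------
# Three-strain closest-pair calls


@dataclass
class AlleleSimilarityCall:
    gene_id: str
    most_similar_pair: Optional[tuple[str, str]]  # strain ids
    pair_label: Optional[str]  # e.g. "A2/A2"
    margin: float
    status: str  # "called" | "ambiguous" | "not_assessed"


def closest_pair_calls(
    gene_id: str,
    alleles: dict[str, Optional[str]],
    labels: dict[str, str],
    scheme: ScoringScheme = NT_SCHEME,
) -> AlleleSimilarityCall:
    """Which pair of three strains carries the most similar alleles of a gene
    (by best local nucleotide alignment score)."""
    strains = sorted(alleles)
    if len(strains) != 3 or any(alleles[s] is None for s in strains):
        return AlleleSimilarityCall(gene_id, None, None, 0.0, "not_assessed")
    pair_scores = {}
    for s1, s2 in itertools.combinations(strains, 2):
        pair_scores[(s1, s2)] = local_score_nt(alleles[s1], alleles[s2], scheme)
    ranked = sorted(pair_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    (best_pair, best_score), (_, second_score) = ranked[0], ranked[1]
    if best_score == second_score:
        return AlleleSimilarityCall(gene_id, None, None, 0.0, "ambiguous")
    label = "/".join(sorted(labels[s] for s in best_pair))
    return AlleleSimilarityCall(gene_id, best_pair, label,
                                best_score - second_score, "called")


# ---------------------------------------------------------------------------
# dS-set comparison (Student's t) and breakpoint contrast


@dataclass
class TTestResult:
    t: float
    df: int
    p: float  # one-sided, alternative mean(between) > mean(within)
    n1: int
    n2: int


def compare_ds_sets(ds_between: Sequence[float],
                    ds_within: Sequence[float]) -> TTestResult:
    """Pooled-variance Student's t-test of the one-sided alternative that
    between-mating-type dS exceeds within-mating-type dS. Undefined dS
    entries must be removed by the caller."""
    x = np.asarray(ds_between, dtype=float)
    y = np.asarray(ds_within, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two dS values per set")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TTestResult(0.0, len(x) + len(y) - 2, 0.5, len(x), len(y))
        p = 0.0 if np.mean(x) > np.mean(y) else 1.0
        t = float("inf") if p == 0.0 else float("-inf")
        return TTestResult(t, len(x) + len(y) - 2, p, len(x), len(y))
    res = stats.ttest_ind(x, y, equal_var=True, alternative="greater")
    return TTestResult(float(res.statistic), len(x) + len(y) - 2,
                       float(res.pvalue), len(x), len(y))


def breakpoint_divergence_test(track: WindowTrack, blocks: SyntenyBlocks,
                               flank_windows: int = 2):
    """Rank-sum test that similarity near inversion breakpoints is lower than
    inside inverted blocks (the suspension-bridge signature of residual
    within-inversion exchange)."""
    from .composition import rank_sum_test

    n = len(track.windows)
    is_breakpoint = [False] * n
    for lo, hi in blocks.breakpoints:
        for i, ((s, e), _) in enumerate(track.windows):
            if s < hi and e > lo:
                for j in range(max(0, i - flank_windows),
                               min(n, i + flank_windows + 1)):
                    is_breakpoint[j] = True
    interior_spans = [b.span_a for b in blocks.blocks if b.orientation == "inverted"]
    bp_vals, interior_vals = [], []
    for i, ((s, e), v) in enumerate(track.windows):
        if is_breakpoint[i]:
            bp_vals.append(v)
        elif any(s >= lo and e <= hi for lo, hi in interior_spans):
            interior_vals.append(v)
    if len(bp_vals) < 3 or len(interior_vals) < 3:
        raise ValueError("insufficient windows in breakpoint or interior class")
    return rank_sum_test(bp_vals, interior_vals, alternative="less")


def ds_table_row(gene_id: str, pair: str, est: DsEstimate) -> str:
    """One TSV row; undefined dS printed as "Un"."""
    def fmt(v: Optional[float]) -> str:
        return "Un" if v is None else f"{v:.4f}"

    return "\t".join([gene_id, pair, fmt(est.dS),
                      fmt(est.SE_dS), fmt(est.dN), fmt(est.SE_dN), est.status])
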