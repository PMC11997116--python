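"""Downstream applications of modification calls.

* jagged-end profiling: 6mA level as a function of distance from the 3' end
  of each strand (end repair of 5' protruding cfDNA ends incorporates 6mA
  into the fill-in segment);
* nucleosome periodicity: binned 6mA level around anchor sites (e.g. CTCF
  binding sites) and autocorrelation-based estimation of the nucleosomal
  repeat length;
* de novo motif enrichment for 6mA (exhaustive short words and gapped word
  pairs, with parsimony reduction and IUPAC merging);
* reference-based molecule-origin scoring: a per-molecule Bernoulli
  log-likelihood ratio comparing each methylation profile with two reference
  classes (e.g. tumor-like vs background tissue).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .calling import MoleculeMethylationProfile, _parse_bed
from .io_smrt import ModificationCall, MoleculeKinetics, revcomp

logger = logging.getLogger("smrtmod")


# ---------------------------------------------------------------------------
# Jagged-end profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndProfile:
    """6mA level per distance from the strand 3' end, pooled over molecules."""

    distances: np.ndarray          # 0..D
    level: np.ndarray              # NaN where no called A at that distance
    n: np.ndarray                  # called A sites per distance

    def mean_level(self, dmin: int, dmax: int) -> float:
        mask = (self.distances >= dmin) & (self.distances <= dmax) & (self.n > 0)
        if not mask.any():
            return float("nan")
        return float(np.average(self.level[mask], weights=self.n[mask]))


def jagged_end_profile(calls: Iterable[ModificationCall],
                       molecules: Iterable[MoleculeKinetics],
                       D: int = 30) -> EndProfile:
    """For each distance d in 0..D from a strand's 3' end, the fraction of
    called adenines labelled modified.  Watson 3' ends are at the right of
    the molecule, Crick 3' ends at the left (Watson coordinate 0)."""
    length = {m.molecule_id: len(m) for m in molecules}
    n = np.zeros(D + 1, dtype=np.int64)
    mod = np.zeros(D + 1, dtype=np.int64)
    for c in calls:
        if c.mod_type != "6mA" or c.label == "no_call":
            continue
        if c.strand_mode == "watson":
            d = length[c.molecule_id] - 1 - c.position
        elif c.strand_mode == "crick":
            d = c.position
        else:
            raise ValueError("jagged-end profiling needs strand-specific calls")
        if 0 <= d <= D:
            n[d] += 1
            mod[d] += c.label == "modified"
    with np.errstate(invalid="ignore"):
        level = np.where(n > 0, mod / np.maximum(n, 1), np.nan)
    return EndProfile(distances=np.arange(D + 1), level=level, n=n)


# ---------------------------------------------------------------------------
# Anchor periodicity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorProfile:
    offsets: np.ndarray            # bin centres, -span..+span
    level: np.ndarray              # NaN where uncovered
    n: np.ndarray
    estimated_period: float | None


def _estimate_period(profile: np.ndarray, bin_size: float,
                     min_peak: float = 0.2,
                     method: str = "autocorrelation") -> float | None:
    """Repeat length of a (possibly noisy) periodic profile.

    ``autocorrelation``: lag of the first local maximum of the normalized,
    mean-subtracted autocorrelation whose height is within 10% of the best
    peak; ``periodogram``: inverse of the dominant non-DC frequency.  Returns
    None when no peak clears ``min_peak``.
    """
    x = profile - np.nanmean(profile)
    x = np.where(np.isfinite(x), x, 0.0)
    if x.size < 3 or np.allclose(x, 0):
        return None
    if method == "periodogram":
        power = np.abs(np.fft.rfft(x)) ** 2
        power[0] = 0.0
        k = int(np.argmax(power))
        if k == 0 or power[k] < min_peak * np.sum(power):
            return None
        return float(x.size * bin_size / k)
    full = np.correlate(x, x, mode="full")
    ac = full[x.size - 1:] / full[x.size - 1]
    peaks = [lag for lag in range(2, ac.size - 1)
             if ac[lag] >= ac[lag - 1] and ac[lag] >= ac[lag + 1]
             and ac[lag] >= min_peak]
    if not peaks:
        return None
    best = max(ac[lag] for lag in peaks)
    first = next(lag for lag in peaks if ac[lag] >= 0.9 * best)
    return float(first * bin_size)


def anchor_periodicity(
    calls: Iterable[ModificationCall],
    anchors: str | Path | Sequence[int],
    molecules: Iterable[MoleculeKinetics] | None = None,
    *,
    span: int = 1000,
    bin_size: int = 10,
    method: str = "autocorrelation",
) -> AnchorProfile:
    """Binned 6mA level vs signed offset from the nearest anchor, with the
    dominant repeat length of the offset profile.

    Anchors are genomic positions (or a BED file of intervals, taken at their
    midpoints); calls are mapped to the genome via each molecule's
    ``ref_start``.  Fewer than 3 covered bins ⇒ period missing.
    """
    if isinstance(anchors, (str, Path)):
        anchor_pos = [(s + e) // 2 for _, s, e, _ in _parse_bed(anchors)]
    else:
        anchor_pos = [int(a) for a in anchors]
    if not anchor_pos:
        raise ValueError("no anchors supplied")
    anchor_arr = np.array(sorted(anchor_pos))
    starts = ({m.molecule_id: m.ref_start for m in molecules}
              if molecules is not None else {})
    n_bins = 2 * (span // bin_size) + 1
    centre = span // bin_size
    n = np.zeros(n_bins, dtype=np.int64)
    mod = np.zeros(n_bins, dtype=np.int64)
    for c in calls:
        if c.label == "no_call":
            continue
        g = starts.get(c.molecule_id, 0) + c.position
        j = int(np.searchsorted(anchor_arr, g))
        best = min((a for a in anchor_arr[max(0, j - 1):j + 1]),
                   key=lambda a: abs(g - a), default=None)
        if best is None:
            continue
        off = g - best
        if abs(off) > span:
            continue
        b = centre + int(round(off / bin_size))
        if 0 <= b < n_bins:
            n[b] += 1
            mod[b] += c.label == "modified"
    with np.errstate(invalid="ignore"):
        level = np.where(n > 0, mod / np.maximum(n, 1), np.nan)
    covered = int((n > 0).sum())
    period = (None if covered < 3
              else _estimate_period(level, bin_size, method=method))
    offsets = (np.arange(n_bins) - centre) * bin_size
    return AnchorProfile(offsets=offsets, level=level, n=n,
                         estimated_period=period)


# ---------------------------------------------------------------------------
# Motif enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifResult:
    motif: str                     # IUPAC word, possibly "LEFT(N)gRIGHT"
    a_index: int                   # index of the modified adenine in the word
    n_sites: int
    level_at_motif: float
    background_level: float
    enrichment: float
    p_value: float                 # binomial vs background, uncorrected


_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AC"): "M", frozenset("AG"): "R",
    frozenset("AT"): "W", frozenset("CG"): "S", frozenset("CT"): "Y",
    frozenset("GT"): "K", frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


def _iupac_consensus(words: Sequence[str]) -> str:
    return "".join(_IUPAC[frozenset(col)] for col in zip(*words))


def _strand_context(seq: str, pos: int, strand: str) -> tuple[str, int]:
    """Sequence and position in the calling strand's own 5'→3' orientation."""
    if strand == "watson":
        return seq, pos
    return revcomp(seq), len(seq) - 1 - pos


def motif_enrichment(
    calls: Iterable[ModificationCall],
    sequences: Mapping[str, str] | Iterable[MoleculeKinetics],
    *,
    k_range: Sequence[int] = (4, 5, 6),
    gapped: bool = False,
    gap_range: tuple[int, int] = (1, 10),
    part_lengths: Sequence[int] = (2, 3, 4),
    min_sites: int = 30,
    alpha: float = 0.05,
    top_n: int = 20,
) -> list[MotifResult]:
    """Rank sequence words by 6mA enrichment at a fixed adenine index.

    For every contiguous ``k``-mer (and optionally every gapped pair
    ``LEFT(N)gRIGHT``) containing the called adenine, the 6mA level across
    its occurrences is compared with the overall adenine background.  Words
    are kept when Bonferroni-significant, reduced to the most parsimonious
    (a word is dropped when an equally enriched shorter subword exists), and
    single-mismatch neighbours with enrichment within 10% are merged into an
    IUPAC consensus.
    """
    if not isinstance(sequences, Mapping):
        sequences = {m.molecule_id: m.sequence for m in sequences}
    counts: dict[tuple[str, int], np.ndarray] = {}
    total = np.zeros(2, dtype=np.int64)  # called, modified

    def bump(key, is_mod):
        c = counts.get(key)
        if c is None:
            c = counts[key] = np.zeros(2, dtype=np.int64)
        c[0] += 1
        c[1] += is_mod

    for c in calls:
        if c.mod_type != "6mA" or c.label == "no_call":
            continue
        seq, p = _strand_context(sequences[c.molecule_id], c.position,
                                 c.strand_mode)
        is_mod = c.label == "modified"
        total[0] += 1
        total[1] += is_mod
        n = len(seq)
        for k in k_range:
            for j in range(k):
                lo = p - j
                if lo < 0 or lo + k > n:
                    continue
                word = seq[lo:lo + k]
                if "N" in word:
                    continue
                bump((word, j), is_mod)
        if gapped:
            for l1 in part_lengths:
                for j in range(l1):
                    lo = p - j
                    if lo < 0:
                        continue
                    left = seq[lo:lo + l1]
                    if len(left) < l1 or "N" in left:
                        continue
                    for g in range(gap_range[0], gap_range[1] + 1):
                        for l2 in part_lengths:
                            rlo = lo + l1 + g
                            right = seq[rlo:rlo + l2]
                            if len(right) < l2 or "N" in right:
                                continue
                            bump((f"{left}(N){g}{right}", j), is_mod)

    if total[0] == 0:
        raise ValueError("no called adenine sites")
    bg = total[1] / total[0]
    eps = 1e-9
    n_tests = max(1, len(counts))

    cands = []
    for (word, j), (called, modified) in counts.items():
        if called < min_sites:
            continue
        level = modified / called
        enr = level / max(bg, eps)
        p_val = float(stats.binom.sf(modified - 1, called, max(bg, eps))) \
            if modified > 0 else 1.0
        if p_val * n_tests < alpha and enr > 1.0:
            cands.append(MotifResult(word, j, int(called), float(level),
                                     float(bg), float(enr), p_val))
    cands.sort(key=lambda m: (-m.enrichment, -m.n_sites, len(m.motif)))

    # parsimony: drop a word when a shorter aligned subword is nearly as enriched
    def contains(big: MotifResult, small: MotifResult) -> bool:
        if "(N)" in big.motif or "(N)" in small.motif:
            return False
        w, s = big.motif, small.motif
        if len(s) >= len(w):
            return False
        start = big.a_index - small.a_index
        return 0 <= start <= len(w) - len(s) and w[start:start + len(s)] == s

    kept: list[MotifResult] = []
    for m in cands:
        shadowed = any(contains(m, u) and u.enrichment >= 0.9 * m.enrichment
                       for u in cands if u is not m)
        if not shadowed:
            kept.append(m)

    # merge single-mismatch neighbours with enrichment within 10%
    merged: list[MotifResult] = []
    used: set[int] = set()
    for i, m in enumerate(kept):
        if i in used:
            continue
        group = [m]
        for k2, other in enumerate(kept[i + 1:], start=i + 1):
            if k2 in used or "(N)" in other.motif or "(N)" in m.motif:
                continue
            if (len(other.motif) == len(m.motif) and other.a_index == m.a_index
                    and sum(a != b for a, b in zip(other.motif, m.motif)) == 1
                    and abs(other.enrichment - m.enrichment)
                    <= 0.1 * m.enrichment):
                group.append(other)
                used.add(k2)
        if len(group) == 1:
            merged.append(m)
        else:
            n_sites = sum(g.n_sites for g in group)
            level = sum(g.level_at_motif * g.n_sites for g in group) / n_sites
            merged.append(MotifResult(
                motif=_iupac_consensus([g.motif for g in group]),
                a_index=m.a_index, n_sites=n_sites, level_at_motif=float(level),
                background_level=m.background_level,
                enrichment=float(level / max(bg, eps)),
                p_value=min(g.p_value for g in group)))
    merged.sort(key=lambda m: (-m.enrichment, -m.n_sites, len(m.motif)))
    return merged[:top_n]


# ---------------------------------------------------------------------------
# Molecule-origin score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferencePanel:
    """Per-site methylation probabilities for two reference classes.

    Keys are produced by ``key_fn(molecule_id, position)`` (default: the
    position alone).  Probabilities are clipped into
    ``(pseudocount, 1 - pseudocount)``.
    """

    prob_a: Mapping[object, float]
    prob_b: Mapping[object, float]
    pseudocount: float = 0.01
    key_fn: Callable[[str, int], object] | None = None

    def __post_init__(self):
        if not (0.0 < self.pseudocount < 0.5):
            raise ValueError("pseudocount must be in (0, 0.5)")

    def lookup(self, molecule_id: str, position: int):
        key = (self.key_fn(molecule_id, position)
               if self.key_fn is not None else position)
        if key not in self.prob_a or key not in self.prob_b:
            return None
        lo, hi = self.pseudocount, 1.0 - self.pseudocount
        return (min(max(self.prob_a[key], lo), hi),
                min(max(self.prob_b[key], lo), hi))

    def swapped(self) -> "ReferencePanel":
        return ReferencePanel(self.prob_b, self.prob_a, self.pseudocount,
                              self.key_fn)


@dataclass(frozen=True)
class OriginScores:
    molecule_scores: dict[str, float]
    sample_score: float | None
    n_molecules_used: int
    n_molecules_excluded: int
    n_sites_skipped: int


def molecule_origin_score(
    profiles: Iterable[MoleculeMethylationProfile],
    panel: ReferencePanel,
    min_cpg: int = 1,
    max_cpg: int | None = None,
) -> OriginScores:
    """Score each molecule's methylation profile against the two panel
    classes.

    The per-molecule score is the mean per-CpG Bernoulli log-likelihood
    ratio (class A vs class B), mapped to [0, 1] by the logistic function;
    the sample score is the mean over molecules.  Molecules with fewer than
    ``min_cpg`` (or more than ``max_cpg``) called CpGs, or with all sites
    missing from the panel, are excluded.
    """
    scores: dict[str, float] = {}
    skipped_sites = 0
    excluded = 0
    for prof in profiles:
        if prof.n_cpg < min_cpg or (max_cpg is not None and prof.n_cpg > max_cpg):
            excluded += 1
            continue
        llr_sum, used = 0.0, 0
        for pos, state in zip(prof.positions, prof.states):
            if state == "no_call":
                continue
            pq = panel.lookup(prof.molecule_id, pos)
            if pq is None:
                skipped_sites += 1
                continue
            pa, pb = pq
            if state == "methylated":
                llr_sum += math.log(pa / pb)
            else:
                llr_sum += math.log((1.0 - pa) / (1.0 - pb))
            used += 1
        if used == 0:
            excluded += 1
            continue
        mean_llr = llr_sum / used
        scores[prof.molecule_id] = 1.0 / (1.0 + math.exp(-mean_llr))
    sample = float(np.mean(list(scores.values()))) if scores else None
    return OriginScores(molecule_scores=scores, sample_score=sample,
                        n_molecules_used=len(scores),
                        n_molecules_excluded=excluded,
                        n_sites_skipped=skipped_sites)
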