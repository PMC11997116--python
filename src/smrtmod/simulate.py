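"""Synthetic SMRT-seq kinetics with ground-truth base modifications.

The generator emulates the phenomenology that modification callers rely on:

* log-normal-like per-base kinetic baselines (IPD and PW), with unmodified
  adenine and thymine sharing one baseline;
* multiplicative kinetic footprints centred on each modified base and decaying
  over a few neighbouring positions (a modified template base slows the
  polymerase at and around the incorporation site);
* per-pass multiplicative noise, so aggregated kinetics sharpen with subread
  depth;
* sequencing adapters flanking every molecule, carrying unmodified baseline
  kinetics;
* modification placement rules: per-CpG Bernoulli (5mC/5xC/5hmC), all-adenine
  (whole-genome-amplification-with-6mA-like libraries), Dam-style GATC 6mA,
  jagged 5' overhangs whose fill-in incorporates 6mA, and periodic
  accessibility-driven 6mA around anchor sites.

Everything is driven by one :class:`numpy.random.Generator`; the same seed
yields byte-identical fixture files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .io_smrt import (
    AdapterFlank,
    MoleculeKinetics,
    SubreadPass,
    aggregate_subreads,
)

logger = logging.getLogger("smrtmod")

#: generic SMRTbell-style hairpin adapter (45 nt)
DEFAULT_ADAPTER = "ATCTCTCTCAACAACAACAACGGAGGAGGAGGAAAAGAGAGAGAT"

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# Kinetic model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticModel:
    """Per-base-identity kinetic baselines plus per-pass noise.

    ``family`` controls the per-site distribution: ``lognormal`` draws
    ``loc * exp(N(0, scale))`` (loc is the median), ``normal`` draws
    ``N(loc, scale)`` truncated at 0, ``uniform`` draws
    ``U(loc - scale, loc + scale)`` truncated at 0.  A modification footprint
    multiplies the location before the draw.  Each pass then multiplies the
    site value by ``exp(N(0, noise_sigma))``.
    """

    family: Literal["lognormal", "normal", "uniform"] = "lognormal"
    ipd: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        # A and T baselines identical on purpose (uA vs T indistinguishable,
        # which is what the thymine-median normalization exploits);
        # uA IPD median anchored at 0.22.
        "A": (0.22, 0.20), "T": (0.22, 0.20),
        "C": (0.25, 0.20), "G": (0.28, 0.20),
    })
    pw: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "A": (0.30, 0.20), "T": (0.30, 0.20),
        "C": (0.32, 0.20), "G": (0.35, 0.20),
    })
    noise_sigma: float = 0.5

    def __post_init__(self):
        if self.family not in ("lognormal", "normal", "uniform"):
            raise ValueError(f"unknown kinetic family {self.family!r}")
        for params in (self.ipd, self.pw):
            for b in _BASES:
                loc, scale = params[b]
                if scale <= 0 or loc <= 0:
                    raise ValueError("kinetic locations and scales must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def site_values(self, rng: np.random.Generator, loc: np.ndarray,
                    scale: np.ndarray) -> np.ndarray:
        if self.family == "lognormal":
            return loc * np.exp(rng.normal(0.0, 1.0, size=loc.shape) * scale)
        if self.family == "normal":
            return np.maximum(loc + rng.normal(0.0, 1.0, size=loc.shape) * scale, 0.0)
        return np.maximum(loc + rng.uniform(-1.0, 1.0, size=loc.shape) * scale, 0.0)


def symmetric_kinetic_model(loc: float = 1.0, scale: float = 0.15,
                            noise_sigma: float = 0.0) -> KineticModel:
    """A truncated-normal model with *identical* symmetric baselines for all
    bases — used to verify that thymine-median normalization centres
    unmodified-adenine signals at 1."""
    params = {b: (loc, scale) for b in _BASES}
    return KineticModel(family="normal", ipd=params, pw=dict(params),
                        noise_sigma=noise_sigma)


# ---------------------------------------------------------------------------
# Modification footprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModificationEffect:
    """Multiplicative kinetic footprint of one modification type.

    The factor at offset ``d`` is ``center ** exp(-d^2 / (2 sigma^2))`` for
    ``|d| <= support`` and 1 beyond — a Gaussian decay in log space with the
    configured central factor.
    """

    mod_type: str
    ipd_center: float
    pw_center: float
    sigma: float = 2.0
    support: int = 5
    strand_scope: Literal["template-strand-only", "both"] = "both"

    def __post_init__(self):
        if self.ipd_center < 1.0 or self.pw_center < 1.0:
            raise ValueError("footprint central factors must be >= 1")
        if self.sigma <= 0 or self.support < 0:
            raise ValueError("invalid footprint shape parameters")

    def _footprint(self, center: float) -> dict[int, float]:
        out = {}
        for d in range(-self.support, self.support + 1):
            out[d] = center ** float(np.exp(-(d * d) / (2.0 * self.sigma ** 2)))
        return out

    @property
    def ipd_footprint(self) -> dict[int, float]:
        return self._footprint(self.ipd_center)

    @property
    def pw_footprint(self) -> dict[int, float]:
        return self._footprint(self.pw_center)


def default_effects() -> dict[str, ModificationEffect]:
    """Default footprints.  The 6mA central IPD factor 4.1 is anchored to the
    observed uA/6mA IPD medians 0.22 vs 0.90; the rest are generator choices."""
    return {
        "6mA": ModificationEffect("6mA", ipd_center=4.1, pw_center=1.3,
                                  strand_scope="template-strand-only"),
        "5mC": ModificationEffect("5mC", ipd_center=1.6, pw_center=1.2),
        "5hmC": ModificationEffect("5hmC", ipd_center=1.3, pw_center=1.1),
    }


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated library."""

    n_molecules: int = 200
    length_mean: float = 200.0
    length_sd: float = 30.0
    min_length: int = 60
    gc: float = 0.45
    cpg_density: float = 0.04          # expected CpG starts per interior bp
    edge_cpg: bool = False             # cycle forced CpGs through end distances 0..21
    depth_mean: int = 20               # per-strand subread depth
    depth_dist: Literal["fixed", "poisson", "uniform"] = "fixed"
    depth_range: tuple[int, int] = (1, 30)
    kinetics: KineticModel = field(default_factory=KineticModel)
    effects: Mapping[str, ModificationEffect] = field(default_factory=default_effects)
    # placement rules -------------------------------------------------------
    rule: Literal["cpg", "all-A", "dam", "jagged", "accessibility"] = "cpg"
    mod_type: str = "5mC"              # for the cpg rule
    p: float = 1.0                     # per-site modification probability
    p_motif: float = 0.95              # dam: GATC adenines (anchored to 95.2%)
    p_bg: float = 0.01                 # dam: background adenines (anchored to 0.87%)
    jag_min: int = 2                   # jagged: J ~ uniform{jag_min..jag_max}
    jag_max: int = 10
    jag_ends: Literal["left", "right", "both"] = "both"
    period: float = 180.0              # accessibility: nucleosomal repeat (bp)
    amplitude: float = 0.4
    base_rate: float = 0.05
    anchors: tuple[int, ...] = ()
    accessibility_span: int = 1000     # elevation only within this distance of an anchor
    genome_length: int = 20000
    # adapters --------------------------------------------------------------
    adapter: str = DEFAULT_ADAPTER
    with_adapters: bool = True
    aggregation: Literal["mean", "median"] = "mean"
    seed: int = 0

    def __post_init__(self):
        for name in ("p", "p_motif", "p_bg", "base_rate", "amplitude"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.amplitude + self.base_rate > 1.0:
            raise ValueError("amplitude + base_rate must not exceed 1")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        if self.jag_min < 0 or self.jag_max < self.jag_min:
            raise ValueError("invalid jag length range")


@dataclass
class GroundTruth:
    """Per-site truth labels for a simulated library.

    ``sites[molecule_id]`` holds ``(position, strand, mod_type)`` triples in
    Watson coordinates; ``strand`` is ``duplex`` for symmetric CpG
    modifications and ``watson``/``crick`` for strand-specific 6mA.
    """

    sites: dict[str, set[tuple[int, str, str]]] = field(default_factory=dict)
    jags: dict[str, tuple[int, int]] = field(default_factory=dict)
    anchors: tuple[int, ...] = ()

    def positions(self, molecule_id: str, strand: str | None = None) -> set[int]:
        out = set()
        for pos, s, _ in self.sites.get(molecule_id, ()):
            if strand is None or s == strand or s == "duplex":
                out.add(pos)
        return out

    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list(_BASES)), size=n, p=p)


def _place_cpgs(rng: np.random.Generator, seq: np.ndarray,
                density: float, forced: Sequence[int] = ()) -> np.ndarray:
    n = seq.shape[0]
    k = rng.poisson(density * n)
    starts = set(int(s) for s in rng.integers(0, n - 1, size=k))
    starts.update(int(f) for f in forced if 0 <= f < n - 1)
    # drop overlaps deterministically (keep the leftmost of a clashing pair)
    kept: list[int] = []
    for s in sorted(starts):
        if not kept or s - kept[-1] >= 2:
            kept.append(s)
    for s in kept:
        seq[s] = "C"
        seq[s + 1] = "G"
    return seq


def cpg_sites(sequence: str) -> list[int]:
    """Watson positions of CpG cytosines."""
    return [i for i in range(len(sequence) - 1)
            if sequence[i] == "C" and sequence[i + 1] == "G"]


def a_sites(sequence: str, strand: str) -> list[int]:
    """Watson-coordinate positions carrying an adenine on the given strand
    (a Crick adenine pairs with a Watson thymine)."""
    want = "A" if strand == "watson" else "T"
    return [i for i, b in enumerate(sequence) if b == want]


# ---------------------------------------------------------------------------
# Kinetics synthesis
# ---------------------------------------------------------------------------

def _log_factor_arrays(length: int, truth: set[tuple[int, str, str]],
                       effects: Mapping[str, ModificationEffect]) -> dict:
    """Per-strand, per-channel multiplicative footprint factors (log space)."""
    lf = {("w", "ipd"): np.zeros(length), ("w", "pw"): np.zeros(length),
          ("c", "ipd"): np.zeros(length), ("c", "pw"): np.zeros(length)}
    for pos, strand, mod in truth:
        eff = effects[mod]
        if eff.strand_scope == "both" or strand == "duplex":
            strands = ("w", "c")
        else:
            strands = ("w",) if strand == "watson" else ("c",)
        for d, f_ipd in eff.ipd_footprint.items():
            j = pos + d
            if 0 <= j < length:
                f_pw = eff.pw_footprint[d]
                for s in strands:
                    lf[(s, "ipd")][j] += np.log(f_ipd)
                    lf[(s, "pw")][j] += np.log(f_pw)
    return lf


def _strand_bases(sequence: str, strand_tag: str) -> list[str]:
    if strand_tag == "w":
        return list(sequence)
    return [_COMP[b] for b in sequence]


def _baseline_locs(km: KineticModel, bases: list[str], channel: str):
    params = km.ipd if channel == "ipd" else km.pw
    loc = np.array([params[b][0] for b in bases])
    scale = np.array([params[b][1] for b in bases])
    return loc, scale


def _synthesize_strand(rng, km: KineticModel, bases: list[str],
                       log_factor_ipd, log_factor_pw, depth: int, agg: str):
    """Draw per-site levels, then per-pass noisy copies, and aggregate."""
    out = {}
    for channel, lf in (("ipd", log_factor_ipd), ("pw", log_factor_pw)):
        loc, scale = _baseline_locs(km, bases, channel)
        site = km.site_values(rng, loc * np.exp(lf), scale)
        if depth > 0:
            if km.noise_sigma > 0:
                noise = np.exp(rng.normal(0.0, km.noise_sigma, size=(depth, len(bases))))
            else:
                noise = np.ones((depth, len(bases)))
            passes = site[None, :] * noise
        else:
            passes = np.zeros((0, len(bases)))
        out[channel] = passes
    return out


def _simulate_molecule(rng, cfg: SimConfig, mol_id: str, sequence: str,
                       truth: set[tuple[int, str, str]], ref_start: int = 0,
                       ) -> MoleculeKinetics:
    n = len(sequence)
    lf = _log_factor_arrays(n, truth, cfg.effects)
    depths = {}
    for tag in ("w", "c"):
        if cfg.depth_dist == "fixed":
            depths[tag] = cfg.depth_mean
        elif cfg.depth_dist == "poisson":
            depths[tag] = max(1, int(rng.poisson(cfg.depth_mean)))
        else:
            lo, hi = cfg.depth_range
            depths[tag] = int(rng.integers(lo, hi + 1))

    passes: list[SubreadPass] = []
    for tag, strand in (("w", "watson"), ("c", "crick")):
        bases = _strand_bases(sequence, tag)
        drawn = _synthesize_strand(rng, cfg.kinetics, bases,
                                   lf[(tag, "ipd")], lf[(tag, "pw")],
                                   depths[tag], cfg.aggregation)
        for k in range(depths[tag]):
            passes.append(SubreadPass(mol_id, strand, k,
                                      drawn["ipd"][k], drawn["pw"][k]))
    kin = aggregate_subreads(passes, cfg.aggregation)

    def flank(adapter_seq: str) -> AdapterFlank:
        zeros = np.zeros(len(adapter_seq))
        parts = {}
        for tag in ("w", "c"):
            bases = _strand_bases(adapter_seq, tag)
            drawn = _synthesize_strand(rng, cfg.kinetics, bases, zeros, zeros,
                                       max(depths[tag], 1), cfg.aggregation)
            aggf = np.mean if cfg.aggregation == "mean" else np.median
            parts[f"ipd_{tag}"] = aggf(drawn["ipd"], axis=0)
            parts[f"pw_{tag}"] = aggf(drawn["pw"], axis=0)
        return AdapterFlank(sequence=adapter_seq, **parts)

    left = flank(cfg.adapter) if cfg.with_adapters else None
    right = flank(cfg.adapter) if cfg.with_adapters else None
    return MoleculeKinetics(
        molecule_id=mol_id, sequence=sequence,
        depth_w=kin["depth_w"], depth_c=kin["depth_c"],
        ipd_w=kin["ipd_w"], pw_w=kin["pw_w"],
        ipd_c=kin["ipd_c"], pw_c=kin["pw_c"],
        adapter_left=left, adapter_right=right, ref_start=ref_start,
    )


def _molecule_length(rng, cfg: SimConfig) -> int:
    return max(cfg.min_length, int(round(rng.normal(cfg.length_mean, cfg.length_sd))))


# ---------------------------------------------------------------------------
# Library generators
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> tuple[list[MoleculeKinetics], GroundTruth]:
    """Generate one library under ``config.rule`` (``cpg`` or ``all-A``);
    the other rules have dedicated generators below."""
    if config.rule == "dam":
        return simulate_dam_genome(config)
    if config.rule == "jagged":
        return simulate_jagged_library(config)
    if config.rule == "accessibility":
        mols, truth, _ = simulate_accessibility_track(config)
        return mols, truth
    if config.rule not in ("cpg", "all-A"):
        raise ValueError(f"unknown placement rule {config.rule!r}")

    rng = np.random.default_rng(config.seed)
    molecules, truth = [], GroundTruth()
    edge_left = 0
    edge_right = 1
    for i in range(config.n_molecules):
        n = _molecule_length(rng, config)
        seq = _random_sequence(rng, n, config.gc)
        forced: list[int] = []
        if config.edge_cpg:
            forced = [edge_left % 22, n - 2 - (edge_right % 21)]
            edge_left += 1
            edge_right += 1
        if config.rule == "cpg":
            seq = _place_cpgs(rng, seq, config.cpg_density, forced)
        sequence = "".join(seq)
        mol_id = f"mol{i:05d}"
        sites: set[tuple[int, str, str]] = set()
        if config.rule == "cpg":
            for pos in cpg_sites(sequence):
                if rng.random() < config.p:
                    sites.add((pos, "duplex", config.mod_type))
        else:  # all-A: 6mA on every adenine of both strands with probability p
            for strand in ("watson", "crick"):
                for pos in a_sites(sequence, strand):
                    if rng.random() < config.p:
                        sites.add((pos, strand, "6mA"))
        truth.sites[mol_id] = sites
        molecules.append(_simulate_molecule(rng, config, mol_id, sequence, sites))
    return molecules, truth


def simulate_dam_genome(config: SimConfig) -> tuple[list[MoleculeKinetics], GroundTruth]:
    """Dam-style 6mA: the adenine of every 5'-GATC-3' occurrence (both strands)
    is methylated with probability ``p_motif``; every other adenine with
    probability ``p_bg``."""
    rng = np.random.default_rng(config.seed)
    molecules, truth = [], GroundTruth()
    for i in range(config.n_molecules):
        n = _molecule_length(rng, config)
        sequence = "".join(_random_sequence(rng, n, config.gc))
        mol_id = f"mol{i:05d}"
        motif_sites: set[tuple[int, str]] = set()
        for j in range(n - 3):
            if sequence[j:j + 4] == "GATC":
                motif_sites.add((j + 1, "watson"))   # GATC, A on Watson
                motif_sites.add((j + 2, "crick"))    # complementary GATC, A on Crick
        sites: set[tuple[int, str, str]] = set()
        for strand in ("watson", "crick"):
            for pos in a_sites(sequence, strand):
                p = config.p_motif if (pos, strand) in motif_sites else config.p_bg
                if rng.random() < p:
                    sites.add((pos, strand, "6mA"))
        truth.sites[mol_id] = sites
        molecules.append(_simulate_molecule(rng, config, mol_id, sequence, sites))
    return molecules, truth


def simulate_jagged_library(config: SimConfig) -> tuple[list[MoleculeKinetics], GroundTruth]:
    """cfDNA-like duplexes with 5' protruding (jagged) ends.

    A left-end jag of length J recesses the Crick 3' end: end repair fills
    Watson positions ``0..J-1`` on the Crick strand with 6mA at every Crick
    adenine.  A right-end jag symmetrically fills Watson positions
    ``L-J..L-1`` on the Watson strand.  ``truth.jags[mol] = (J_left, J_right)``.
    """
    rng = np.random.default_rng(config.seed)
    molecules, truth = [], GroundTruth()
    for i in range(config.n_molecules):
        n = _molecule_length(rng, config)
        sequence = "".join(_random_sequence(rng, n, config.gc))
        mol_id = f"mol{i:05d}"

        def draw_jag() -> int:
            for _ in range(100):
                j = int(rng.integers(config.jag_min, config.jag_max + 1))
                if j < n:
                    return j
                logger.warning("molecule %s: jag %d >= length %d, resampled",
                               mol_id, j, n)
            raise ValueError(f"molecule {mol_id}: cannot draw jag < length {n}")

        j_left = draw_jag() if config.jag_ends in ("left", "both") else 0
        j_right = draw_jag() if config.jag_ends in ("right", "both") else 0
        sites: set[tuple[int, str, str]] = set()
        for pos in range(j_left):
            if sequence[pos] == "T":          # Crick adenine
                sites.add((pos, "crick", "6mA"))
        for pos in range(n - j_right, n):
            if sequence[pos] == "A":
                sites.add((pos, "watson", "6mA"))
        truth.sites[mol_id] = sites
        truth.jags[mol_id] = (j_left, j_right)
        molecules.append(_simulate_molecule(rng, config, mol_id, sequence, sites))
    return molecules, truth


def simulate_accessibility_track(
    config: SimConfig,
) -> tuple[list[MoleculeKinetics], GroundTruth, tuple[int, ...]]:
    """Accessibility-driven 6mA around anchor sites.

    Within ``accessibility_span`` of the nearest anchor, the per-adenine
    modification probability is ``base_rate + amplitude * (1 + cos(2*pi*d /
    period)) / 2`` at anchor distance ``d`` (raised cosine, clipped to [0,1]);
    beyond the span it is ``base_rate``.  Molecules are placed uniformly on a
    linear genome of ``genome_length`` bp.
    """
    rng = np.random.default_rng(config.seed)
    anchors = config.anchors or (config.genome_length // 2,)
    molecules, truth = [], GroundTruth(anchors=tuple(anchors))
    anchor_arr = np.array(anchors, dtype=float)
    n_elevated = 0
    for i in range(config.n_molecules):
        n = _molecule_length(rng, config)
        start = int(rng.integers(0, max(1, config.genome_length - n)))
        sequence = "".join(_random_sequence(rng, n, config.gc))
        mol_id = f"mol{i:05d}"
        sites: set[tuple[int, str, str]] = set()
        for strand in ("watson", "crick"):
            for pos in a_sites(sequence, strand):
                g = start + pos
                d = np.min(np.abs(anchor_arr - g))
                if d <= config.accessibility_span:
                    w = 0.5 * (1.0 + np.cos(2.0 * np.pi * d / config.period))
                    p = min(1.0, config.base_rate + config.amplitude * w)
                    n_elevated += 1
                else:
                    p = config.base_rate
                if rng.random() < p:
                    sites.add((pos, strand, "6mA"))
        truth.sites[mol_id] = sites
        molecules.append(_simulate_molecule(rng, config, mol_id, sequence, sites,
                                            ref_start=start))
    if n_elevated == 0:
        logger.warning("no adenine site fell within %d bp of any anchor",
                       config.accessibility_span)
    return molecules, truth, tuple(anchors)
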