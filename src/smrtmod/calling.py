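"""Per-site calling workflows.

Wraps feature construction and a trained scorer into the workflows used in
practice: duplex or strand-specific 5mC calling, two-stage resolution of
cytosine modifications (unmodified vs modified, then 5mC vs 5hmC), iterative
6mA calling with confounder masking, and aggregation of calls to region
levels and per-molecule methylation profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import (
    NormalizationSpec,
    build_windows,
    default_norm,
    target_positions,
)
from .io_smrt import ModificationCall, MoleculeKinetics, StrandMode
from .model import TrainedModel

logger = logging.getLogger("smrtmod")


@dataclass(frozen=True)
class CallConfig:
    cutoff: float = 0.5
    strand_mode: StrandMode = "duplex"
    use_adapters: bool = True
    width: int = 21
    max_6mA_iterations: int = 3

    def __post_init__(self):
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must be in (0, 1)")
        if self.max_6mA_iterations < 1:
            raise ValueError("max_6mA_iterations must be >= 1")


def _check_model(model: TrainedModel, mod_type: str, cfg: CallConfig) -> None:
    if model.mod_type != mod_type:
        raise ValueError(f"model was trained for {model.mod_type}, not {mod_type}")
    # single-strand windows are extracted in the strand's own 5'→3'
    # orientation, so one single-strand model serves watson and crick alike
    single = ("watson", "crick")
    compatible = (model.strand_mode == cfg.strand_mode
                  or (model.strand_mode in single and cfg.strand_mode in single))
    if not compatible:
        raise ValueError(f"model strand mode {model.strand_mode!r} does not "
                         f"match requested {cfg.strand_mode!r}")


def _strand_depth(mol: MoleculeKinetics, strand_mode: StrandMode) -> int:
    if strand_mode == "watson":
        return mol.depth_w
    if strand_mode == "crick":
        return mol.depth_c
    return min(mol.depth_w, mol.depth_c)


def _label(score: float, cutoff: float) -> str:
    return "modified" if score > cutoff else "unmodified"


# ---------------------------------------------------------------------------
# 5mC
# ---------------------------------------------------------------------------

def call_5mC(mol: MoleculeKinetics, model: TrainedModel,
             cfg: CallConfig = CallConfig()) -> list[ModificationCall]:
    """One call per CpG cytosine; sites without an intact window (adapters
    off near fragment ends) are emitted as no_call records."""
    _check_model(model, "5mC", cfg)
    if cfg.strand_mode == "duplex" and (mol.depth_w == 0 or mol.depth_c == 0):
        logger.warning("molecule %s has a zero-depth strand; duplex calling "
                       "unavailable, emitting no_calls (use a single-strand "
                       "model instead)", mol.molecule_id)
        return [ModificationCall(mol.molecule_id, p, cfg.strand_mode, "5mC",
                                 None, "no_call", 0)
                for p in target_positions(mol, "5mC", cfg.strand_mode)]
    positions = target_positions(mol, "5mC", cfg.strand_mode)
    if not positions:
        return []
    X, valid = build_windows(
        mol, positions, mod_type="5mC", strand_mode=cfg.strand_mode,
        width=cfg.width, use_adapters=cfg.use_adapters,
        norm=default_norm("5mC"))
    depth = _strand_depth(mol, cfg.strand_mode)
    calls = []
    scores = model.predict(X[valid]) if valid.any() else np.zeros(0)
    it = iter(scores)
    for p, v in zip(positions, valid):
        if v:
            s = float(next(it))
            calls.append(ModificationCall(mol.molecule_id, p, cfg.strand_mode,
                                          "5mC", s, _label(s, cfg.cutoff), depth))
        else:
            calls.append(ModificationCall(mol.molecule_id, p, cfg.strand_mode,
                                          "5mC", None, "no_call", depth))
    return calls


# ---------------------------------------------------------------------------
# Two-stage 5hmC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineResolution:
    """Three-way cytosine call with both stage scores retained."""

    molecule_id: str
    position: int
    strand_mode: StrandMode
    stage1_score: float | None   # unmodified vs modified (5xC)
    stage2_score: float | None   # 5mC vs 5hmC (gated on stage 1)
    call: str                    # "uC" | "5mC" | "5hmC" | "no_call"
    depth: int = 0


def call_5hmC_two_stage(mol: MoleculeKinetics, stage1_model: TrainedModel,
                        stage2_model: TrainedModel,
                        cfg: CallConfig = CallConfig(),
                        stage2_cutoff: float | None = None,
                        ) -> list[CytosineResolution]:
    """Resolve each CpG into uC / 5mC / 5hmC.

    Stage 1 scores unmodified-vs-modified cytosine: a score at or below the
    cutoff is uC.  Otherwise stage 2 (5mC vs 5hmC, modified class = 5hmC)
    decides: score above the (stage-2) cutoff is 5hmC, else 5mC.
    """
    if stage1_model.mod_type != "5xC":
        raise ValueError("stage-1 model must be trained for 5xC (uC vs modified)")
    if stage2_model.mod_type != "5hmC":
        raise ValueError("stage-2 model must be trained for 5hmC (5mC vs 5hmC)")
    for m in (stage1_model, stage2_model):
        if m.strand_mode != cfg.strand_mode:
            raise ValueError("model strand mode mismatch")
        if (m.layout, m.width) != (stage1_model.layout, stage1_model.width):
            raise ValueError("stage models must share a feature layout")
    c2 = cfg.cutoff if stage2_cutoff is None else stage2_cutoff
    positions = target_positions(mol, "5xC", cfg.strand_mode)
    if not positions:
        return []
    X, valid = build_windows(
        mol, positions, mod_type="5xC", strand_mode=cfg.strand_mode,
        width=cfg.width, use_adapters=cfg.use_adapters,
        norm=default_norm("5xC"))
    depth = _strand_depth(mol, cfg.strand_mode)
    out = []
    if valid.any():
        s1 = stage1_model.predict(X[valid])
        s2 = stage2_model.predict(X[valid])
    i = 0
    for p, v in zip(positions, valid):
        if not v:
            out.append(CytosineResolution(mol.molecule_id, p, cfg.strand_mode,
                                          None, None, "no_call", depth))
            continue
        a, b = float(s1[i]), float(s2[i])
        i += 1
        if a <= cfg.cutoff:
            out.append(CytosineResolution(mol.molecule_id, p, cfg.strand_mode,
                                          a, None, "uC", depth))
        else:
            call = "5hmC" if b > c2 else "5mC"
            out.append(CytosineResolution(mol.molecule_id, p, cfg.strand_mode,
                                          a, b, call, depth))
    return out


# ---------------------------------------------------------------------------
# Iterative 6mA
# ---------------------------------------------------------------------------

def call_6mA_iterative(mol: MoleculeKinetics, model: TrainedModel,
                       cfg: CallConfig | None = None) -> list[ModificationCall]:
    """Score all adenines of one strand, then iterate: adenines provisionally
    called modified become declared confounding sites for the next round's
    normalization (masked to 1, excluding the target itself), until the label
    set is stable or ``max_6mA_iterations`` is reached."""
    if cfg is None:
        cfg = CallConfig(strand_mode=model.strand_mode)  # type: ignore[arg-type]
    _check_model(model, "6mA", cfg)
    if cfg.strand_mode == "duplex":
        raise ValueError("6mA calling is strand-specific; use watson or crick")
    positions = target_positions(mol, "6mA", cfg.strand_mode)
    if not positions:
        return []
    depth = _strand_depth(mol, cfg.strand_mode)
    confounders: frozenset[int] = frozenset()
    prev_modified: set[int] | None = None
    scores = np.zeros(0)
    valid = np.zeros(len(positions), dtype=bool)
    for _ in range(cfg.max_6mA_iterations):
        norm = default_norm("6mA", confounder_positions=confounders)
        X, valid = build_windows(
            mol, positions, mod_type="6mA", strand_mode=cfg.strand_mode,
            width=cfg.width, use_adapters=cfg.use_adapters, norm=norm)
        scores = model.predict(X[valid]) if valid.any() else np.zeros(0)
        modified = {p for p, s in zip(np.array(positions)[valid], scores)
                    if s > cfg.cutoff}
        if modified == prev_modified:
            break
        prev_modified = modified
        confounders = frozenset(modified)
    calls = []
    it = iter(scores)
    for p, v in zip(positions, valid):
        if v:
            s = float(next(it))
            calls.append(ModificationCall(mol.molecule_id, p, cfg.strand_mode,
                                          "6mA", s, _label(s, cfg.cutoff), depth))
        else:
            calls.append(ModificationCall(mol.molecule_id, p, cfg.strand_mode,
                                          "6mA", None, "no_call", depth))
    return calls


def apply_cutoff(calls: Iterable[ModificationCall],
                 cutoff: float) -> list[ModificationCall]:
    """Relabel calls at a new cutoff; scores are untouched and no_call
    records pass through."""
    out = []
    for c in calls:
        if c.label == "no_call":
            out.append(c)
        else:
            out.append(replace(c, label=_label(c.score, cutoff)))
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _parse_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    regions = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from e
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            regions.append((f[0], start, end, f[3] if len(f) > 3 else f"region{lineno}"))
    return regions


def region_level(
    calls: Iterable[ModificationCall],
    regions: str | Path | Sequence[tuple],
    molecules: Iterable[MoleculeKinetics] | None = None,
) -> dict[str, float | None]:
    """Modification level per region: modified / (modified + unmodified),
    no_call excluded; regions with zero covered sites are ``None`` (missing).

    Calls are mapped onto the reference axis via each molecule's
    ``(ref_name, ref_start)``; without ``molecules`` the molecule_id is taken
    as the reference name and positions as reference positions.
    """
    if isinstance(regions, (str, Path)):
        regs = _parse_bed(regions)
    else:
        regs = [(r[0], int(r[1]), int(r[2]),
                 r[3] if len(r) > 3 else f"region{i + 1}")
                for i, r in enumerate(regions)]
    offsets = {}
    if molecules is not None:
        offsets = {m.molecule_id: (m.ref_name, m.ref_start) for m in molecules}
    counts = {name: [0, 0] for _, _, _, name in regs}
    for c in calls:
        if c.label == "no_call":
            continue
        ref, pos = offsets.get(c.molecule_id, (c.molecule_id, 0))
        g = pos + c.position
        for chrom, start, end, name in regs:
            if chrom == ref and start <= g < end:
                counts[name][c.label != "modified"] += 1
    out: dict[str, float | None] = {}
    for name, (mod, unmod) in counts.items():
        out[name] = mod / (mod + unmod) if mod + unmod else None
    return out


@dataclass(frozen=True)
class MoleculeMethylationProfile:
    """Ordered per-CpG methylation states of one molecule."""

    molecule_id: str
    positions: tuple[int, ...]
    states: tuple[str, ...]      # "methylated" | "unmethylated" | "no_call"

    @property
    def n_cpg(self) -> int:
        """Number of *called* CpG sites."""
        return sum(s != "no_call" for s in self.states)

    @property
    def binary(self) -> tuple[int, ...]:
        """Called sites only, 1 = methylated."""
        return tuple(1 if s == "methylated" else 0
                     for s in self.states if s != "no_call")


def molecule_profiles(calls: Iterable[ModificationCall],
                      ) -> list[MoleculeMethylationProfile]:
    """Group 5mC calls into per-molecule ordered profiles; molecules whose
    sites are all no_call are excluded (logged)."""
    by_mol: dict[str, list[ModificationCall]] = {}
    for c in calls:
        if c.mod_type != "5mC":
            raise ValueError("molecule_profiles expects 5mC calls")
        by_mol.setdefault(c.molecule_id, []).append(c)
    out = []
    state_of = {"modified": "methylated", "unmodified": "unmethylated",
                "no_call": "no_call"}
    for mid, cs in sorted(by_mol.items()):
        cs.sort(key=lambda c: c.position)
        states = tuple(state_of[c.label] for c in cs)
        if all(s == "no_call" for s in states):
            logger.info("molecule %s: all CpG sites no_call; profile excluded", mid)
            continue
        out.append(MoleculeMethylationProfile(
            molecule_id=mid, positions=tuple(c.position for c in cs),
            states=states))
    return out
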