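"""Measurement-window construction and kinetic normalization.

A *measurement window* is the model input for one candidate site: a
``width x channels`` matrix covering ``(width-1)/2`` nt on each side of the
target (default 21 nt), combining normalized IPD/PW kinetics, one-hot base
identities, an adapter flag, and a relative-position channel.

Two normalization schemes are provided:

* ``median50`` (cytosine modifications): each kinetic channel is divided by
  its median over a 50-nt span centred on the target, making windows
  invariant to molecule-wide kinetic scale.
* ``thymine-median`` (6mA): every kinetic value is divided by the median
  kinetic value of thymines on the same strand within the span.  Unmodified
  adenines share the thymine baseline, so their normalized values centre at 1;
  declared *confounding sites* (neighbouring modified adenines) are then set
  to exactly 1, maximally resembling the unmodified-adenine distribution.

Windows whose span would extend past the fragment end are completed from the
flanking sequencing-adapter kinetics when available (``adapter_flag = 1`` on
those rows); otherwise the site is a no-call (``valid = False``).

Channel layouts (versioned; trained models are layout-bound):

* ``duplex-v1``:  [ipd_w, pw_w, ipd_c, pw_c, A, C, G, T, adapter, relpos]
* ``single-v1``:  [ipd, pw, A, C, G, T, adapter, relpos]

Crick-strand kinetics in duplex windows are base-paired aligned: row *i*
carries the Crick kinetics of the base pairing Watson position *i*.  Crick
single-strand windows are extracted in the Crick strand's own 5'→3'
orientation (reverse-complemented view), so one single-strand model serves
both strands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .io_smrt import MoleculeKinetics, ModType, StrandMode

logger = logging.getLogger("smrtmod")

DUPLEX_LAYOUT = "duplex-v1"
SINGLE_LAYOUT = "single-v1"

DUPLEX_CHANNELS = ("ipd_w", "pw_w", "ipd_c", "pw_c",
                   "A", "C", "G", "T", "adapter", "relpos")
SINGLE_CHANNELS = ("ipd", "pw", "A", "C", "G", "T", "adapter", "relpos")

_N_KIN = {DUPLEX_LAYOUT: 4, SINGLE_LAYOUT: 2}


def layout_channels(layout: str) -> tuple[str, ...]:
    if layout == DUPLEX_LAYOUT:
        return DUPLEX_CHANNELS
    if layout == SINGLE_LAYOUT:
        return SINGLE_CHANNELS
    raise ValueError(f"unknown feature layout {layout!r}")


@dataclass(frozen=True)
class NormalizationSpec:
    """How kinetic channels are normalized within a window."""

    mode: Literal["median50", "thymine-median"] = "median50"
    span: int = 50
    epsilon: float = 1e-3
    clamp: float = 10.0
    confounder_positions: frozenset[int] = frozenset()

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.mode not in ("median50", "thymine-median"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")


@dataclass(frozen=True)
class MeasurementWindow:
    """Feature matrix for one target site (``matrix is None`` iff invalid)."""

    molecule_id: str
    position: int
    mod_type: ModType | None
    strand_mode: StrandMode
    width: int
    layout: str
    matrix: np.ndarray | None
    valid: bool
    depths: tuple[int, int] = (0, 0)   # (watson, crick) subread depth

    def require_valid(self) -> np.ndarray:
        if not self.valid or self.matrix is None:
            raise ValueError(
                f"window at {self.molecule_id}:{self.position} is a no-call")
        return self.matrix


# ---------------------------------------------------------------------------
# Extended coordinate view (adapter_left + molecule + adapter_right)
# ---------------------------------------------------------------------------

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_COMP_IDX = {0: 3, 1: 2, 2: 1, 3: 0, -1: -1}


class _ExtView:
    """Concatenated adapter+molecule+adapter arrays in Watson coordinates.

    Molecule positions map to extended index ``pos + offset``.
    """

    def __init__(self, mol: MoleculeKinetics, use_adapters: bool):
        parts_seq = []
        kin = {k: [] for k in ("ipd_w", "pw_w", "ipd_c", "pw_c")}
        left = mol.adapter_left if use_adapters else None
        right = mol.adapter_right if use_adapters else None
        if left is not None:
            parts_seq.append(left.sequence)
            for k in kin:
                kin[k].append(getattr(left, k))
        parts_seq.append(mol.sequence)
        for k in kin:
            kin[k].append(getattr(mol, k))
        if right is not None:
            parts_seq.append(right.sequence)
            for k in kin:
                kin[k].append(getattr(right, k))
        self.offset = len(left) if left is not None else 0
        self.mol_len = len(mol)
        self.n = self.offset + self.mol_len + (len(right) if right is not None else 0)
        self.base_idx = np.array([_BASE_IDX[b] for b in "".join(parts_seq)],
                                 dtype=np.int64)
        self.kin = {k: np.concatenate(v) for k, v in kin.items()}

    def flipped(self) -> "_ExtView":
        """The reverse-complement view (Crick strand read 5'→3')."""
        out = object.__new__(_ExtView)
        out.n = self.n
        out.mol_len = self.mol_len
        out.offset = self.n - self.offset - self.mol_len
        out.base_idx = np.array([_COMP_IDX[i] for i in self.base_idx[::-1]],
                                dtype=np.int64)
        out.kin = {
            "ipd_w": self.kin["ipd_c"][::-1].copy(),
            "pw_w": self.kin["pw_c"][::-1].copy(),
            "ipd_c": self.kin["ipd_w"][::-1].copy(),
            "pw_c": self.kin["pw_w"][::-1].copy(),
        }
        return out


def _check_target_bases(mol: MoleculeKinetics, positions: np.ndarray,
                        mod_type: ModType | None, strand_mode: StrandMode) -> None:
    if mod_type is None:
        return
    seq = mol.sequence
    n = len(seq)
    for pos in positions:
        p = int(pos)
        if not (0 <= p < n):
            raise ValueError(f"position {p} out of range for molecule "
                             f"{mol.molecule_id} (length {n})")
        if mod_type == "6mA":
            want = "A" if strand_mode in ("duplex", "watson") else "T"
            if seq[p] != want:
                raise ValueError(
                    f"molecule {mol.molecule_id} position {p}: base {seq[p]} "
                    f"is not an adenine on the {strand_mode} strand")
        else:
            if strand_mode == "crick":
                ok = p >= 1 and seq[p] == "G" and seq[p - 1] == "C"
            else:
                ok = seq[p] == "C" and (strand_mode == "watson"
                                        or (p + 1 < n and seq[p + 1] == "G"))
            if not ok:
                raise ValueError(
                    f"molecule {mol.molecule_id} position {p}: base {seq[p]} "
                    f"does not match a {mod_type} target in {strand_mode} mode")


# ---------------------------------------------------------------------------
# Batch window construction (the workhorse)
# ---------------------------------------------------------------------------

def build_windows(
    mol: MoleculeKinetics,
    positions: Sequence[int],
    *,
    mod_type: ModType | None = None,
    strand_mode: StrandMode = "duplex",
    width: int = 21,
    use_adapters: bool = True,
    norm: NormalizationSpec | None = None,
    check_bases: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (and optionally normalize) windows for many positions of one
    molecule.

    Returns ``(X, valid)`` where ``X`` has shape ``(n, width, channels)``
    (rows of invalid windows are zero) and ``valid`` is a boolean mask.
    """
    if width % 2 != 1 or width < 3:
        raise ValueError("width must be an odd integer >= 3")
    if norm is not None and norm.span < width:
        raise ValueError("normalization span must be >= window width")
    positions = np.asarray(positions, dtype=np.int64)
    if check_bases:
        _check_target_bases(mol, positions, mod_type, strand_mode)
    elif np.any((positions < 0) | (positions >= len(mol))):
        raise ValueError(f"position out of range for molecule {mol.molecule_id}")

    ext = _ExtView(mol, use_adapters)
    if strand_mode == "crick":
        ext = ext.flipped()
        ext_positions = (len(mol) - 1 - positions) + ext.offset
        conf = (frozenset(len(mol) - 1 - c for c in norm.confounder_positions)
                if norm is not None else frozenset())
        mol_positions = len(mol) - 1 - positions
    else:
        ext_positions = positions + ext.offset
        conf = norm.confounder_positions if norm is not None else frozenset()
        mol_positions = positions

    h = (width - 1) // 2
    idx = ext_positions[:, None] + np.arange(-h, h + 1)[None, :]
    valid = np.all((idx >= 0) & (idx < ext.n), axis=1)
    cidx = np.clip(idx, 0, ext.n - 1)

    n_pos = positions.shape[0]
    layout = DUPLEX_LAYOUT if strand_mode == "duplex" else SINGLE_LAYOUT
    channels = layout_channels(layout)
    X = np.zeros((n_pos, width, len(channels)))

    if strand_mode == "duplex":
        kin_cols = [("ipd_w", 0), ("pw_w", 1), ("ipd_c", 2), ("pw_c", 3)]
        base_at = 4
    else:
        kin_cols = [("ipd_w", 0), ("pw_w", 1)]
        base_at = 2
    for k, col in kin_cols:
        X[:, :, col] = ext.kin[k][cidx]
    bases = ext.base_idx[cidx]
    for b in range(4):
        X[:, :, base_at + b] = (bases == b)
    in_adapter = (cidx < ext.offset) | (cidx >= ext.offset + ext.mol_len)
    X[:, :, base_at + 4] = in_adapter
    X[:, :, base_at + 5] = (np.arange(-h, h + 1) / h)[None, :]

    if norm is not None:
        kin_channel_ids = [c for _, c in kin_cols]
        _normalize_in_place(X, valid, ext, ext_positions, mol_positions, conf,
                            kin_channel_ids, norm, strand_mode, width,
                            mol.molecule_id)

    X[~valid] = 0.0
    return X, valid


def _span_indices(ext: _ExtView, ext_positions: np.ndarray, span: int):
    rel = np.arange(span) - span // 2
    sidx = ext_positions[:, None] + rel[None, :]
    in_range = (sidx >= 0) & (sidx < ext.n)
    return np.clip(sidx, 0, ext.n - 1), in_range


def _normalize_in_place(X, valid, ext, ext_positions, mol_positions, conf,
                        kin_channel_ids, norm: NormalizationSpec,
                        strand_mode, width, mol_id) -> None:
    sidx, in_range = _span_indices(ext, ext_positions, norm.span)

    if norm.mode == "median50":
        # per kinetic channel: divide by the span median of that channel
        kin_names = (["ipd_w", "pw_w", "ipd_c", "pw_c"]
                     if strand_mode == "duplex" else ["ipd_w", "pw_w"])
        for k, col in zip(kin_names, kin_channel_ids):
            vals = np.where(in_range, ext.kin[k][sidx], np.nan)
            med = np.nanmedian(vals, axis=1)
            if np.any(med == 0):
                logger.warning("molecule %s: all-zero %s channel over a "
                               "normalization span", mol_id, k)
            X[:, :, col] /= np.maximum(med, norm.epsilon)[:, None]
    else:
        # thymine-median: one divisor per kinetic channel, computed over the
        # thymine positions of the same strand within the span
        if strand_mode == "duplex":
            raise ValueError("thymine-median normalization is strand-specific; "
                             "use watson or crick mode")
        is_t = ext.base_idx[sidx] == 3
        t_mask = in_range & is_t
        any_t = t_mask.any(axis=1)
        mol_t = ext.base_idx[ext.offset:ext.offset + ext.mol_len] == 3
        for k, col in zip(["ipd_w", "pw_w"], kin_channel_ids):
            vals = np.where(t_mask, ext.kin[k][sidx], np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.nanmedian(vals, axis=1)
            if not np.all(any_t):
                # fall back to the molecule-wide thymine median
                mol_vals = ext.kin[k][ext.offset:ext.offset + ext.mol_len][mol_t]
                if mol_vals.size == 0:
                    raise ValueError(
                        f"molecule {mol_id}: no thymines available for "
                        "thymine-median normalization")
                med = np.where(any_t, med, np.median(mol_vals))
            X[:, :, col] /= np.maximum(med, norm.epsilon)[:, None]

    for col in kin_channel_ids:
        np.clip(X[:, :, col], 0.0, norm.clamp, out=X[:, :, col])

    if conf:
        # mask declared confounding sites (molecule coordinates on the
        # processed strand) to exactly 1, excluding the target itself
        h = (width - 1) // 2
        offs = np.arange(-h, h + 1)
        row_mol_pos = mol_positions[:, None] + offs[None, :]
        conf_arr = np.array(sorted(conf), dtype=np.int64)
        is_conf = np.isin(row_mol_pos, conf_arr) & (offs[None, :] != 0)
        for col in kin_channel_ids:
            X[:, :, col][is_conf] = 1.0


# ---------------------------------------------------------------------------
# Single-window operations
# ---------------------------------------------------------------------------

def extract_window(
    mol: MoleculeKinetics,
    position: int,
    *,
    width: int = 21,
    strand_mode: StrandMode = "duplex",
    use_adapters: bool = True,
    mod_type: ModType | None = None,
    norm: NormalizationSpec | None = None,
) -> MeasurementWindow:
    """Window for a single target site (no-call ⇒ ``valid=False``)."""
    X, valid = build_windows(mol, [position], mod_type=mod_type,
                             strand_mode=strand_mode, width=width,
                             use_adapters=use_adapters, norm=norm)
    layout = DUPLEX_LAYOUT if strand_mode == "duplex" else SINGLE_LAYOUT
    ok = bool(valid[0])
    return MeasurementWindow(
        molecule_id=mol.molecule_id, position=position, mod_type=mod_type,
        strand_mode=strand_mode, width=width, layout=layout,
        matrix=X[0] if ok else None, valid=ok,
        depths=(mol.depth_w, mol.depth_c),
    )


def _renormalized(window: MeasurementWindow, mol: MoleculeKinetics,
                  spec: NormalizationSpec) -> MeasurementWindow:
    return extract_window(
        mol, window.position, width=window.width,
        strand_mode=window.strand_mode, use_adapters=True,
        mod_type=window.mod_type, norm=spec,
    )


def normalize_median50(window: MeasurementWindow, mol: MoleculeKinetics,
                       spec: NormalizationSpec) -> MeasurementWindow:
    """Divide each kinetic channel by its median over the span centred on the
    target (floored at ``spec.epsilon``), leaving identity/flag/position
    channels untouched."""
    if spec.mode != "median50":
        raise ValueError("spec.mode must be 'median50'")
    return _renormalized(window, mol, spec)


def normalize_by_thymine(window: MeasurementWindow, mol: MoleculeKinetics,
                         spec: NormalizationSpec) -> MeasurementWindow:
    """6mA normalization: divide every kinetic value by the same-strand
    thymine median over the span, then set declared confounding sites to 1."""
    if spec.mode != "thymine-median":
        raise ValueError("spec.mode must be 'thymine-median'")
    if window.mod_type not in (None, "6mA"):
        raise ValueError("thymine-median normalization applies to 6mA targets")
    return _renormalized(window, mol, spec)


def encode_duplex(window_w: MeasurementWindow,
                  window_c: MeasurementWindow) -> MeasurementWindow:
    """Combine Watson- and Crick-strand windows for the same target into a
    duplex matrix (Crick kinetics base-paired aligned in Watson coordinates,
    base one-hot from the Watson strand)."""
    if window_w.strand_mode != "watson" or window_c.strand_mode != "crick":
        raise ValueError("encode_duplex expects a watson and a crick window")
    if (window_w.molecule_id, window_w.position) != (window_c.molecule_id,
                                                     window_c.position):
        raise ValueError("windows must target the same site")
    if window_w.width != window_c.width:
        raise ValueError("window width mismatch")
    dw, dc = window_w.depths
    if dc == 0:
        raise ValueError("Crick subread depth is 0: use watson-only mode")
    if dw == 0:
        raise ValueError("Watson subread depth is 0: use crick-only mode")
    if not (window_w.valid and window_c.valid):
        return MeasurementWindow(
            molecule_id=window_w.molecule_id, position=window_w.position,
            mod_type=window_w.mod_type, strand_mode="duplex",
            width=window_w.width, layout=DUPLEX_LAYOUT, matrix=None,
            valid=False, depths=window_w.depths)
    mw = window_w.require_valid()
    mc = window_c.require_valid()[::-1]  # back to Watson coordinate order
    width = window_w.width
    X = np.zeros((width, len(DUPLEX_CHANNELS)))
    X[:, 0] = mw[:, 0]   # ipd_w
    X[:, 1] = mw[:, 1]   # pw_w
    X[:, 2] = mc[:, 0]   # ipd_c, base-paired aligned
    X[:, 3] = mc[:, 1]
    X[:, 4:8] = mw[:, 2:6]
    X[:, 8] = mw[:, 6]
    X[:, 9] = mw[:, 7]
    return MeasurementWindow(
        molecule_id=window_w.molecule_id, position=window_w.position,
        mod_type=window_w.mod_type, strand_mode="duplex", width=width,
        layout=DUPLEX_LAYOUT, matrix=X, valid=True, depths=window_w.depths)


# ---------------------------------------------------------------------------
# Site enumeration
# ---------------------------------------------------------------------------

def target_positions(mol: MoleculeKinetics, mod_type: ModType,
                     strand_mode: StrandMode = "duplex") -> list[int]:
    """All candidate target positions for a modification type."""
    seq = mol.sequence
    if mod_type == "6mA":
        want = "A" if strand_mode in ("duplex", "watson") else "T"
        return [i for i, b in enumerate(seq) if b == want]
    if strand_mode == "crick":
        return [i for i in range(1, len(seq)) if seq[i] == "G" and seq[i - 1] == "C"]
    return [i for i in range(len(seq) - 1)
            if seq[i] == "C" and seq[i + 1] == "G"]


def callable_sites(mol: MoleculeKinetics, mod_type: ModType,
                   *, width: int = 21, use_adapters: bool = True,
                   strand_mode: StrandMode = "duplex") -> list[int]:
    """Target positions whose measurement window is intact.

    With adapter padding enabled and adapter flanks present this is *all*
    target positions (100% callable); without it, sites within
    ``(width-1)/2`` nt of a fragment end are no-calls.
    """
    cand = target_positions(mol, mod_type, strand_mode)
    if not cand:
        return []
    _, valid = build_windows(mol, cand, mod_type=mod_type,
                             strand_mode=strand_mode, width=width,
                             use_adapters=use_adapters)
    return [p for p, v in zip(cand, valid) if v]


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def window_dataset(
    molecules: Iterable[MoleculeKinetics],
    sites: Mapping[str, Sequence[int]] | None,
    *,
    mod_type: ModType,
    strand_mode: StrandMode = "duplex",
    width: int = 21,
    use_adapters: bool = True,
    norm: NormalizationSpec | None = None,
    confounders: Mapping[str, frozenset[int]] | None = None,
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Stack valid windows across molecules.

    ``sites`` maps molecule_id → target positions (``None`` = all candidate
    positions).  ``confounders`` optionally maps molecule_id → positions to
    mask during thymine-median normalization.  Returns ``(X, index)`` with
    ``index[i] = (molecule_id, position)`` for row ``i``.
    """
    mats, index = [], []
    for mol in molecules:
        if sites is None:
            pos = target_positions(mol, mod_type, strand_mode)
        else:
            pos = list(sites.get(mol.molecule_id, ()))
        if not pos:
            continue
        mol_norm = norm
        if norm is not None and confounders is not None:
            cset = frozenset(confounders.get(mol.molecule_id, frozenset()))
            mol_norm = NormalizationSpec(
                mode=norm.mode, span=norm.span, epsilon=norm.epsilon,
                clamp=norm.clamp, confounder_positions=cset)
        X, valid = build_windows(mol, pos, mod_type=mod_type,
                                 strand_mode=strand_mode, width=width,
                                 use_adapters=use_adapters, norm=mol_norm)
        mats.append(X[valid])
        index.extend((mol.molecule_id, p) for p, v in zip(pos, valid) if v)
    if not mats:
        n_ch = len(layout_channels(
            DUPLEX_LAYOUT if strand_mode == "duplex" else SINGLE_LAYOUT))
        return np.zeros((0, width, n_ch)), []
    return np.concatenate(mats, axis=0), index


def default_norm(mod_type: ModType,
                 confounder_positions: frozenset[int] = frozenset()
                 ) -> NormalizationSpec:
    """The normalization a caller should use for a modification type."""
    if mod_type == "6mA":
        return NormalizationSpec(mode="thymine-median",
                                 confounder_positions=confounder_positions)
    return NormalizationSpec(mode="median50")
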