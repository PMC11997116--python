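"""Molecule kinetics I/O and subread aggregation.

Single-molecule real-time (SMRT) sequencing reads a circularized duplex template
many times; each polymerase pass yields a *subread* whose per-base inter-pulse
durations (IPD) and pulse widths (PW) carry the kinetic footprint of template
base modifications.  This module defines the in-memory containers used
throughout the package (:class:`SubreadPass`, :class:`MoleculeKinetics`,
:class:`ModificationCall`), aggregates per-pass kinetics onto consensus
coordinates, and reads/writes two on-disk representations:

* ``tsv-fixture`` — a plain-text, one-line-per-molecule format (canonical for
  tests; round-trips bit-for-bit at 6 significant digits);
* ``bam-kinetics`` — BAM records carrying PacBio-style per-base kinetics tags
  (``fi``/``fp`` for the Watson strand, ``ri``/``rp`` for the Crick strand).

Conventions
-----------
All coordinates are 0-based half-open.  Crick-strand kinetics are stored in
Watson coordinates: the value at index ``i`` belongs to the Crick base paired
with Watson position ``i``.  Subread depth per strand is the number of passes
aggregated for that strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

logger = logging.getLogger("smrtmod")

Strand = Literal["watson", "crick"]
ModType = Literal["5mC", "5xC", "5hmC", "6mA"]
StrandMode = Literal["duplex", "watson", "crick"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: minimum adapter flank length able to complete any default 21-nt window
MIN_ADAPTER_LEN = 10


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _as_float_array(x, name: str, n: int | None = None) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite and non-negative")
    if n is not None and a.shape[0] != n:
        raise ValueError(f"{name} has length {a.shape[0]}, expected {n}")
    return a


@dataclass(frozen=True)
class SubreadPass:
    """Kinetics from one polymerase pass, aligned to consensus coordinates."""

    molecule_id: str
    strand: Strand
    pass_index: int
    ipd: np.ndarray
    pw: np.ndarray
    aligned: bool = True

    def __post_init__(self):
        if self.strand not in ("watson", "crick"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.pass_index < 0:
            raise ValueError("pass_index must be >= 0")
        ipd = _as_float_array(self.ipd, "ipd")
        pw = _as_float_array(self.pw, "pw", ipd.shape[0])
        object.__setattr__(self, "ipd", ipd)
        object.__setattr__(self, "pw", pw)


@dataclass(frozen=True)
class AdapterFlank:
    """Kinetics of a sequencing-adapter segment flanking the molecule.

    Oriented so that ``adapter_left + molecule + adapter_right`` is
    coordinate-continuous on the Watson strand.
    """

    sequence: str
    ipd_w: np.ndarray
    pw_w: np.ndarray
    ipd_c: np.ndarray
    pw_c: np.ndarray

    def __post_init__(self):
        n = len(self.sequence)
        if n < MIN_ADAPTER_LEN:
            raise ValueError(
                f"adapter flank must be >= {MIN_ADAPTER_LEN} nt, got {n}"
            )
        for name in ("ipd_w", "pw_w", "ipd_c", "pw_c"):
            object.__setattr__(self, name, _as_float_array(getattr(self, name), name, n))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MoleculeKinetics:
    """One sequenced molecule: consensus sequence + per-strand aggregated kinetics."""

    molecule_id: str
    sequence: str
    ipd_w: np.ndarray
    pw_w: np.ndarray
    ipd_c: np.ndarray
    pw_c: np.ndarray
    depth_w: int
    depth_c: int
    adapter_left: AdapterFlank | None = None
    adapter_right: AdapterFlank | None = None
    #: optional placement on a reference axis (used by region/anchor analyses)
    ref_name: str = "sim"
    ref_start: int = 0

    def __post_init__(self):
        n = len(self.sequence)
        if n == 0:
            raise ValueError(f"molecule {self.molecule_id}: empty sequence")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"molecule {self.molecule_id}: invalid bases in sequence")
        for name in ("ipd_w", "pw_w", "ipd_c", "pw_c"):
            try:
                setattr(self, name, _as_float_array(getattr(self, name), name, n))
            except ValueError as e:
                raise ValueError(f"molecule {self.molecule_id}: {e}") from e
        if self.depth_w < 0 or self.depth_c < 0:
            raise ValueError(f"molecule {self.molecule_id}: negative depth")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "MoleculeKinetics":
        """The same duplex viewed from the opposite strand (strands swapped,
        coordinates reversed).  Applying this twice restores the original."""
        left = self.adapter_right
        right = self.adapter_left

        def flip(fl: AdapterFlank | None) -> AdapterFlank | None:
            if fl is None:
                return None
            return AdapterFlank(
                sequence=revcomp(fl.sequence),
                ipd_w=fl.ipd_c[::-1].copy(),
                pw_w=fl.pw_c[::-1].copy(),
                ipd_c=fl.ipd_w[::-1].copy(),
                pw_c=fl.pw_w[::-1].copy(),
            )

        return MoleculeKinetics(
            molecule_id=self.molecule_id,
            sequence=revcomp(self.sequence),
            ipd_w=self.ipd_c[::-1].copy(),
            pw_w=self.pw_c[::-1].copy(),
            ipd_c=self.ipd_w[::-1].copy(),
            pw_c=self.pw_w[::-1].copy(),
            depth_w=self.depth_c,
            depth_c=self.depth_w,
            adapter_left=flip(left),
            adapter_right=flip(right),
            ref_name=self.ref_name,
            ref_start=self.ref_start,
        )

    def scaled(self, c: float) -> "MoleculeKinetics":
        """All raw kinetics multiplied by ``c`` (used by scale-invariance checks)."""
        if c <= 0:
            raise ValueError("scale factor must be positive")

        def sflank(fl: AdapterFlank | None):
            if fl is None:
                return None
            return AdapterFlank(fl.sequence, fl.ipd_w * c, fl.pw_w * c,
                                fl.ipd_c * c, fl.pw_c * c)

        return replace(
            self,
            ipd_w=self.ipd_w * c, pw_w=self.pw_w * c,
            ipd_c=self.ipd_c * c, pw_c=self.pw_c * c,
            adapter_left=sflank(self.adapter_left),
            adapter_right=sflank(self.adapter_right),
        )


@dataclass(frozen=True)
class ModificationCall:
    """A per-site modification call.

    ``label == "modified"`` iff ``score > cutoff`` (the cutoff is recorded in
    run metadata, not on the call).  ``no_call`` entries carry ``score=None``.
    """

    molecule_id: str
    position: int
    strand_mode: StrandMode
    mod_type: ModType
    score: float | None
    label: Literal["modified", "unmodified", "no_call"]
    depth: int = 0

    def __post_init__(self):
        if self.label == "no_call":
            if self.score is not None:
                raise ValueError("no_call implies score is absent")
        else:
            if self.score is None or not (0.0 <= self.score <= 1.0):
                raise ValueError("score must be in [0, 1]")


# ---------------------------------------------------------------------------
# Subread aggregation
# ---------------------------------------------------------------------------

def aggregate_subreads(
    passes: Sequence[SubreadPass],
    method: Literal["mean", "median"] = "mean",
) -> dict:
    """Aggregate per-pass kinetics onto consensus coordinates.

    Returns the kinetics fields of a :class:`MoleculeKinetics` as a dict
    (``ipd_w``, ``pw_w``, ``ipd_c``, ``pw_c``, ``depth_w``, ``depth_c``);
    strands with zero passes get zero arrays and depth 0.
    """
    if not passes:
        raise ValueError("cannot aggregate an empty collection of passes")
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    mol_ids = {p.molecule_id for p in passes}
    if len(mol_ids) != 1:
        raise ValueError(f"passes span multiple molecules: {sorted(mol_ids)}")
    lengths = {p.ipd.shape[0] for p in passes}
    if len(lengths) != 1:
        raise ValueError(f"mixed pass lengths {sorted(lengths)} for molecule {passes[0].molecule_id}")
    if not all(p.aligned for p in passes):
        raise ValueError("all passes must be aligned to consensus coordinates")
    n = lengths.pop()
    agg = np.mean if method == "mean" else np.median
    out: dict = {}
    for strand, tag in (("watson", "w"), ("crick", "c")):
        sel = [p for p in passes if p.strand == strand]
        if sel:
            out[f"ipd_{tag}"] = agg(np.stack([p.ipd for p in sel]), axis=0)
            out[f"pw_{tag}"] = agg(np.stack([p.pw for p in sel]), axis=0)
        else:
            out[f"ipd_{tag}"] = np.zeros(n)
            out[f"pw_{tag}"] = np.zeros(n)
        out[f"depth_{tag}"] = len(sel)
    return out


# ---------------------------------------------------------------------------
# TSV fixture format
# ---------------------------------------------------------------------------

_KIN_COLS = ("ipd_w", "pw_w", "ipd_c", "pw_c")
_ADAPTER_COLS = tuple(
    f"adapter_{side}_{f}" for side in ("left", "right")
    for f in ("seq", "ipd_w", "pw_w", "ipd_c", "pw_c")
)
_FIXTURE_HEADER = (
    ("molecule_id", "sequence") + _KIN_COLS + ("depth_w", "depth_c", "ref_name", "ref_start")
    + _ADAPTER_COLS
)


def _fmt_floats(a: np.ndarray) -> str:
    return ",".join(format(v, ".6g") for v in a)


def _parse_floats(s: str, name: str, mol: str, n: int | None = None) -> np.ndarray:
    if s == "":
        return np.zeros(0)
    try:
        a = np.array([float(v) for v in s.split(",")], dtype=float)
    except ValueError as e:
        raise ValueError(f"molecule {mol}: malformed field {name}") from e
    if n is not None and a.shape[0] != n:
        raise ValueError(f"molecule {mol}: field {name} has length {a.shape[0]}, expected {n}")
    return a


def write_fixture(molecules: Iterable[MoleculeKinetics], path: str | Path) -> None:
    """Write molecules in the canonical plain-text fixture format."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_FIXTURE_HEADER) + "\n")
        for m in molecules:
            row = [m.molecule_id, m.sequence]
            row += [_fmt_floats(getattr(m, c)) for c in _KIN_COLS]
            row += [str(m.depth_w), str(m.depth_c), m.ref_name, str(m.ref_start)]
            for fl in (m.adapter_left, m.adapter_right):
                if fl is None:
                    row += ["", "", "", "", ""]
                else:
                    row += [fl.sequence, _fmt_floats(fl.ipd_w), _fmt_floats(fl.pw_w),
                            _fmt_floats(fl.ipd_c), _fmt_floats(fl.pw_c)]
            fh.write("\t".join(row) + "\n")


def _read_fixture(path: Path) -> Iterator[MoleculeKinetics]:
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _FIXTURE_HEADER:
            raise ValueError(f"{path}: not a smrtmod tsv-fixture (bad header)")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_FIXTURE_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(_FIXTURE_HEADER)} fields")
            rec = dict(zip(_FIXTURE_HEADER, fields))
            mid = rec["molecule_id"]
            n = len(rec["sequence"])
            kin = {c: _parse_floats(rec[c], c, mid, n) for c in _KIN_COLS}
            flanks = {}
            for side in ("left", "right"):
                seq = rec[f"adapter_{side}_seq"]
                if seq:
                    na = len(seq)
                    flanks[side] = AdapterFlank(
                        sequence=seq,
                        **{f: _parse_floats(rec[f"adapter_{side}_{f}"],
                                            f"adapter_{side}_{f}", mid, na)
                           for f in ("ipd_w", "pw_w", "ipd_c", "pw_c")},
                    )
                else:
                    flanks[side] = None
            mol = MoleculeKinetics(
                molecule_id=mid,
                sequence=rec["sequence"],
                depth_w=int(rec["depth_w"]),
                depth_c=int(rec["depth_c"]),
                adapter_left=flanks["left"],
                adapter_right=flanks["right"],
                ref_name=rec["ref_name"],
                ref_start=int(rec["ref_start"]),
                **kin,
            )
            yield mol


# ---------------------------------------------------------------------------
# BAM with per-base kinetics tags
# ---------------------------------------------------------------------------

def write_bam(molecules: Iterable[MoleculeKinetics], path: str | Path) -> None:
    """Write one unaligned BAM record per molecule with per-base kinetics tags.

    Watson kinetics go to ``fi``/``fp``, Crick kinetics (Watson coordinates) to
    ``ri``/``rp``; per-strand depths are stored in ``dw``/``dc``.  Kinetics are
    scaled by 1000 into integer "frame" units, the convention used by
    instrument BAMs.
    """
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "RG": [{"ID": "smrtmod", "PL": "PACBIO"}]}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for m in molecules:
            a = pysam.AlignedSegment()
            a.query_name = m.molecule_id
            a.query_sequence = m.sequence
            a.is_unmapped = True
            a.set_tag("RG", "smrtmod")
            a.set_tag("fi", [int(round(v * 1000)) for v in m.ipd_w])
            a.set_tag("fp", [int(round(v * 1000)) for v in m.pw_w])
            a.set_tag("ri", [int(round(v * 1000)) for v in m.ipd_c])
            a.set_tag("rp", [int(round(v * 1000)) for v in m.pw_c])
            a.set_tag("dw", m.depth_w)
            a.set_tag("dc", m.depth_c)
            bam.write(a)


def _read_bam(path: Path) -> Iterator[MoleculeKinetics]:
    import pysam

    with pysam.AlignmentFile(str(path), "rb", check_sq=False) as bam:
        for rec in bam:
            seq = rec.query_sequence
            if seq is None:
                raise ValueError(f"BAM record {rec.query_name}: missing sequence")
            n = len(seq)
            kin = {}
            for tag, col in (("fi", "ipd_w"), ("fp", "pw_w"),
                             ("ri", "ipd_c"), ("rp", "pw_c")):
                if not rec.has_tag(tag):
                    raise ValueError(f"BAM record {rec.query_name}: missing tag {tag}")
                vals = np.asarray(rec.get_tag(tag), dtype=float) / 1000.0
                if vals.shape[0] != n:
                    raise ValueError(
                        f"BAM record {rec.query_name}: tag {tag} length "
                        f"{vals.shape[0]} != sequence length {n}")
                kin[col] = vals
            yield MoleculeKinetics(
                molecule_id=rec.query_name,
                sequence=seq,
                depth_w=int(rec.get_tag("dw")) if rec.has_tag("dw") else 1,
                depth_c=int(rec.get_tag("dc")) if rec.has_tag("dc") else 1,
                **kin,
            )


def read_molecules(
    path: str | Path,
    format: Literal["bam-kinetics", "tsv-fixture"] = "tsv-fixture",
) -> Iterator[MoleculeKinetics]:
    """Stream molecules from disk; molecules with zero passes on both strands
    are skipped with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv-fixture":
        it = _read_fixture(path)
    elif format == "bam-kinetics":
        it = _read_bam(path)
    else:
        raise ValueError(f"unknown molecule format {format!r}")
    for mol in it:
        if mol.depth_w == 0 and mol.depth_c == 0:
            logger.warning("molecule %s has zero passes on both strands; skipped",
                           mol.molecule_id)
            continue
        yield mol


# ---------------------------------------------------------------------------
# Call output
# ---------------------------------------------------------------------------

_CALL_TSV_HEADER = ("molecule_id", "position", "strand_mode", "mod_type",
                    "score", "label", "depth")


def write_calls(
    calls: Iterable[ModificationCall],
    path: str | Path,
    format: Literal["bed", "tsv"] = "bed",
) -> None:
    """Write calls sorted by (molecule_id, position, strand_mode).

    BED output is BED6+2: 0-based half-open, name = mod_type, score column =
    1000 × modification score rounded, strand from strand_mode (duplex → "."),
    then raw score and depth.  TSV keeps full precision and no_call rows.
    """
    path = Path(path)
    rows = sorted(calls, key=lambda c: (c.molecule_id, c.position, c.strand_mode))
    with path.open("w") as fh:
        if format == "tsv":
            fh.write("\t".join(_CALL_TSV_HEADER) + "\n")
            for c in rows:
                score = "" if c.score is None else format_score(c.score)
                fh.write(f"{c.molecule_id}\t{c.position}\t{c.strand_mode}\t"
                         f"{c.mod_type}\t{score}\t{c.label}\t{c.depth}\n")
        elif format == "bed":
            strand_sym = {"duplex": ".", "watson": "+", "crick": "-"}
            for c in rows:
                if c.label == "no_call":
                    continue
                fh.write(f"{c.molecule_id}\t{c.position}\t{c.position + 1}\t"
                         f"{c.mod_type}\t{round(1000 * c.score)}\t"
                         f"{strand_sym[c.strand_mode]}\t{format_score(c.score)}\t"
                         f"{c.depth}\n")
        else:
            raise ValueError(f"unknown call format {format!r}")


def format_score(s: float) -> str:
    return format(s, ".6f")


def read_calls_tsv(path: str | Path) -> list[ModificationCall]:
    path = Path(path)
    calls = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _CALL_TSV_HEADER:
            raise ValueError(f"{path}: not a smrtmod calls TSV")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            calls.append(ModificationCall(
                molecule_id=f[0], position=int(f[1]), strand_mode=f[2],  # type: ignore[arg-type]
                mod_type=f[3], score=float(f[4]) if f[4] else None,  # type: ignore[arg-type]
                label=f[5], depth=int(f[6]),  # type: ignore[arg-type]
            ))
    return calls
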