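"""Atomic models, fibril stacking, composites and secondary-structure maps.

This module carries the structural side of the pipeline: reading PDB/mmCIF
coordinate files, cutting out residue ranges (e.g. a sub-domain of a globular
fold), replicating a single fibril layer by helical symmetry (rise + twist
along the fibril axis), assembling composite "chimera" models from parts of
different structures, and classifying/bookkeeping secondary structure.

Conventions
-----------
* Residue numbering is taken verbatim from the input file; ranges are 1-based
  and inclusive everywhere.
* The fibril axis is +z.  Layer 0 sits at the origin; layer k is translated
  k*rise along z and rotated k*twist about z.  Stacked chains are relabeled
  ``<orig>0, <orig>1, ...`` and the central layer (index n//2) is recorded so
  that peak enumeration can use a central-layer-vs-all convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Span",
    "SecondaryStructureMap",
    "FibrilGeometry",
    "CompositeModel",
    "read_structure",
    "select_residues",
    "build_fibril_stack",
    "build_composite",
    "assign_secondary_structure",
    "strand_census",
    "coverage_fraction",
    "load_span_map",
    "read_span_map",
    "parse_ranges",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class Atom:
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class Structure:
    """A set of atoms with chain/residue identity.

    ``metadata`` may carry ``central_chains`` (set of chain ids) for stacked
    fibril models.
    """

    atoms: list[Atom]
    model_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.atom_name)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates for atom {key}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    @property
    def residue_numbers(self) -> list[int]:
        return sorted({a.residue_number for a in self.atoms})

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def atom(self, chain_id: str, residue_number: int, atom_name: str) -> Atom:
        for a in self.atoms:
            if (
                a.chain_id == chain_id
                and a.residue_number == residue_number
                and a.atom_name == atom_name
            ):
                return a
        raise KeyError((chain_id, residue_number, atom_name))


@dataclass(frozen=True)
class Span:
    start: int
    end: int
    kind: str  # helix | three10 | strand | coil
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"span start {self.start} > end {self.end}")
        if self.kind not in {"helix", "three10", "strand", "coil"}:
            raise ValueError(f"unknown span kind {self.kind!r}")

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1


@dataclass
class SecondaryStructureMap:
    spans: list[Span]

    def __post_init__(self) -> None:
        by_kind: dict[str, list[Span]] = {}
        for s in self.spans:
            by_kind.setdefault(s.kind, []).append(s)
        for kind, spans in by_kind.items():
            spans = sorted(spans, key=lambda s: s.start)
            for a, b in zip(spans, spans[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping {kind} spans {a.label or a.start}–{a.end} "
                        f"and {b.label or b.start}–{b.end}"
                    )

    def kind_of(self, residue_number: int) -> str:
        for s in self.spans:
            if s.start <= residue_number <= s.end:
                return s.kind
        return "coil"


@dataclass(frozen=True)
class FibrilGeometry:
    """Helical symmetry of an in-register stack: ~4.7 Å rise per layer."""

    rise_per_layer: float = 4.7
    twist_per_layer: float = 0.0
    n_layers: int = 1

    def __post_init__(self) -> None:
        if self.rise_per_layer <= 0:
            raise ValueError("rise_per_layer must be > 0")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


@dataclass
class CompositeModel:
    """A chimera: parts of different structures claiming disjoint residues."""

    parts: list[tuple[Structure, list[tuple[int, int]], str]]

    @property
    def n_residues_claimed(self) -> int:
        return sum(hi - lo + 1 for _, ranges, _ in self.parts for lo, hi in ranges)

    def part_structures(self) -> list[tuple[str, Structure]]:
        return [
            (label, select_residues(s, ranges)) for s, ranges, label in self.parts
        ]


# ---------------------------------------------------------------------------
# readers


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read the first model of a PDB or mmCIF file into a :class:`Structure`.

    HETATM records and waters are dropped.  Raises ``ValueError`` if no atoms
    survive filtering.
    """
    import gemmi

    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if format not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown format {format!r}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, OSError) as exc:
        raise ValueError(f"unreadable structure file {path}: {exc}") from exc
    atoms: list[Atom] = []
    if len(st) > 0:
        model = st[0]
        for chain in model:
            for res in chain:
                if res.het_flag == "H" or res.name in _WATER_NAMES:
                    continue
                for at in res:
                    atoms.append(
                        Atom(
                            chain_id=chain.name,
                            residue_number=res.seqid.num,
                            residue_name=res.name,
                            atom_name=at.name,
                            element=at.element.name,
                            xyz=(at.pos.x, at.pos.y, at.pos.z),
                        )
                    )
    if not atoms:
        raise ValueError(f"zero atoms after filtering in {path}")
    return Structure(atoms=atoms, model_label=path.stem)


def parse_ranges(text: str) -> list[tuple[int, int]]:
    """Parse a range expression like ``"22-34,50-128"`` into (lo, hi) pairs."""
    ranges = []
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk:
            lo, hi = chunk.split("-", 1)
            ranges.append((int(lo), int(hi)))
        else:
            ranges.append((int(chunk), int(chunk)))
    for lo, hi in ranges:
        if lo > hi:
            raise ValueError(f"inverted range {lo}-{hi}")
    return ranges


def select_residues(
    s: Structure,
    ranges: Sequence[tuple[int, int]] | str,
    allow_empty: bool = False,
) -> Structure:
    """Keep atoms whose residue number falls in any range (all chains)."""
    if isinstance(ranges, str):
        ranges = parse_ranges(ranges)
    for lo, hi in ranges:
        if lo > hi:
            raise ValueError(f"inverted range {lo}-{hi}")
    kept = [
        a
        for a in s.atoms
        if any(lo <= a.residue_number <= hi for lo, hi in ranges)
    ]
    if not kept:
        msg = f"ranges {ranges} select zero atoms from {s.model_label!r}"
        if not allow_empty:
            raise ValueError(msg)
        warnings.warn(msg)
    return Structure(atoms=kept, model_label=s.model_label, metadata=dict(s.metadata))


# ---------------------------------------------------------------------------
# fibril stacking


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_fibril_stack(layer: Structure, g: FibrilGeometry) -> Structure:
    """Replicate one layer into an ``n_layers`` stack along +z.

    Layer k is rotated ``k * twist_per_layer`` about z and translated
    ``k * rise_per_layer`` along z.  Chains are relabeled ``<chain>k`` and the
    central layer (index ``n_layers // 2``) is recorded in
    ``metadata["central_chains"]``.
    """
    if len(layer) == 0:
        raise ValueError("empty layer")
    atoms: list[Atom] = []
    central = g.n_layers // 2
    central_chains: set[str] = set()
    base = layer.coords()
    for k in range(g.n_layers):
        rot = _rot_z(k * g.twist_per_layer)
        xyz = base @ rot.T
        xyz[:, 2] += k * g.rise_per_layer
        for a, p in zip(layer.atoms, xyz):
            cid = f"{a.chain_id}{k}"
            atoms.append(replace(a, chain_id=cid, xyz=(p[0], p[1], p[2])))
            if k == central:
                central_chains.add(cid)
    meta = dict(layer.metadata)
    meta["central_chains"] = sorted(central_chains)
    meta["geometry"] = g
    return Structure(atoms=atoms, model_label=f"{layer.model_label}_stack{g.n_layers}", metadata=meta)


def build_composite(
    parts: Sequence[tuple[Structure, Sequence[tuple[int, int]] | str, str]],
) -> CompositeModel:
    """Assemble a chimera from (structure, residue ranges, label) parts.

    A residue number claimed by two parts is an error (the composite's
    spectrum is later computed as the sum of per-part spectra, so every
    residue must belong to exactly one part).
    """
    norm_parts: list[tuple[Structure, list[tuple[int, int]], str]] = []
    claimed: dict[int, str] = {}
    for s, ranges, label in parts:
        if isinstance(ranges, str):
            ranges = parse_ranges(ranges)
        present = set(s.residue_numbers)
        for lo, hi in ranges:
            in_range = [r for r in range(lo, hi + 1) if r in present]
            if not in_range:
                raise ValueError(
                    f"range {lo}-{hi} of part {label!r} matches no residues "
                    f"in {s.model_label!r}"
                )
            for r in range(lo, hi + 1):
                if r in claimed:
                    raise ValueError(
                        f"residue {r} claimed by both {claimed[r]!r} and {label!r}"
                    )
                claimed[r] = label
        norm_parts.append((s, list(ranges), label))
    return CompositeModel(parts=norm_parts)


# ---------------------------------------------------------------------------
# secondary structure

# (phi, psi) windows of the simplified dihedral classifier, degrees
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_STRAND_PHI = (-180.0, -80.0)
_STRAND_PSI_A = (80.0, 180.0)
_STRAND_PSI_B = (-180.0, -170.0)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def _backbone_by_residue(s: Structure, chain_id: str) -> dict[int, dict[str, np.ndarray]]:
    out: dict[int, dict[str, np.ndarray]] = {}
    for a in s.atoms:
        if a.chain_id != chain_id or a.atom_name not in {"N", "CA", "C"}:
            continue
        out.setdefault(a.residue_number, {})[a.atom_name] = np.array(a.xyz)
    return out


def assign_secondary_structure(s: Structure) -> SecondaryStructureMap:
    """Classify each residue as helix/strand/coil from backbone dihedrals.

    A simplified (phi, psi)-window classifier: runs shorter than 3 residues
    are demoted to coil; residues with missing backbone atoms are coil (with a
    warning).  Intended for idealized synthetic structures — curated span maps
    remain the authority for experimental models.
    """
    all_spans: list[Span] = []
    for chain_id in s.chain_ids:
        bb = _backbone_by_residue(s, chain_id)
        res_nums = sorted(bb)
        labels: dict[int, str] = {}
        for i, r in enumerate(res_nums):
            prev_r = res_nums[i - 1] if i > 0 else None
            next_r = res_nums[i + 1] if i + 1 < len(res_nums) else None
            here = bb[r]
            has = (
                {"N", "CA", "C"} <= set(here)
                and prev_r is not None
                and "C" in bb.get(prev_r, {})
                and next_r is not None
                and "N" in bb.get(next_r, {})
            )
            if not has:
                if {"N", "CA", "C"} - set(here):
                    warnings.warn(
                        f"residue {chain_id}:{r} missing backbone atoms; coil"
                    )
                labels[r] = "coil"
                continue
            phi = dihedral(bb[prev_r]["C"], here["N"], here["CA"], here["C"])
            psi = dihedral(here["N"], here["CA"], here["C"], bb[next_r]["N"])
            if _HELIX_PHI[0] <= phi <= _HELIX_PHI[1] and _HELIX_PSI[0] <= psi <= _HELIX_PSI[1]:
                labels[r] = "helix"
            elif _STRAND_PHI[0] <= phi <= _STRAND_PHI[1] and (
                _STRAND_PSI_A[0] <= psi <= _STRAND_PSI_A[1]
                or _STRAND_PSI_B[0] <= psi <= _STRAND_PSI_B[1]
            ):
                labels[r] = "strand"
            else:
                labels[r] = "coil"
        # demote runs < 3 to coil, then merge into spans
        runs: list[tuple[int, int, str]] = []
        for r in res_nums:
            kind = labels[r]
            if runs and runs[-1][2] == kind and r == runs[-1][1] + 1:
                runs[-1] = (runs[-1][0], r, kind)
            else:
                runs.append((r, r, kind))
        for start, end, kind in runs:
            if kind == "coil":
                continue
            if end - start + 1 < 3:
                continue  # demoted to coil: simply not emitted as a span
            all_spans.append(Span(start, end, kind, label=f"{chain_id}:{kind}"))
    # multiple chains with identical numbering (e.g. fibril layers) produce
    # identical spans; keep one copy of each
    unique: dict[tuple[int, int, str], Span] = {}
    for sp in all_spans:
        unique.setdefault((sp.start, sp.end, sp.kind), sp)
    return SecondaryStructureMap(spans=sorted(unique.values(), key=lambda x: (x.start, x.kind)))


def strand_census(m: SecondaryStructureMap) -> tuple[int, int]:
    """Number of strand spans and the residues they cover."""
    strands = [s for s in m.spans if s.kind == "strand"]
    return len(strands), sum(s.n_residues for s in strands)


def coverage_fraction(
    modeled_ranges: Iterable[tuple[int, int]],
    extra_unassigned: int,
    sequence_length: int,
) -> float:
    """Fraction of the sequence covered by modeled ranges plus unassigned density.

    ``(sum of range lengths + extra_unassigned) / sequence_length``; the
    ranges must be non-overlapping.
    """
    ranges = sorted(modeled_ranges)
    for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
        if b0 <= a1:
            raise ValueError(f"overlapping ranges {a0}-{a1} and {b0}-{b1}")
    covered = sum(hi - lo + 1 for lo, hi in ranges) + extra_unassigned
    return covered / sequence_length


# ---------------------------------------------------------------------------
# span-map files


def read_span_map(path: str | Path) -> SecondaryStructureMap:
    """Read a 4-column span file: start, end, kind, label (tab-separated)."""
    spans = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed span line: {line!r}")
        start, end, kind = int(parts[0]), int(parts[1]), parts[2]
        label = parts[3] if len(parts) > 3 else ""
        spans.append(Span(start, end, kind, label))
    return SecondaryStructureMap(spans=spans)


def load_span_map(name: str) -> SecondaryStructureMap:
    """Load a packaged span map: ``native_human``, ``human_fibril`` or ``hewl_fibril``."""
    from importlib.resources import files

    resource = files("amyloidsim").joinpath("data", f"{name}.tsv")
    if not resource.is_file():
        raise ValueError(f"no packaged span map named {name!r}")
    spans = []
    for line in resource.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        spans.append(Span(int(parts[0]), int(parts[1]), parts[2], parts[3] if len(parts) > 3 else ""))
    return SecondaryStructureMap(spans=spans)
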