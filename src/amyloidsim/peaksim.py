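"""Enumeration of 2D correlation peaks from a structural model plus shifts.

Supported experiment types:

* 13C-13C (DARR-like): one cross peak per ordered carbon pair within a
  distance cutoff (default 5 Å), plus diagonal peaks; peaks can be filtered to
  intra-residue or inter-residue contributions only.
* N-CA / N-CB (NC-CP-like): one bond-mediated peak per residue; no distance
  criterion.
* 15N-13C through-space (PAIN-like): N-C pairs within the cutoff, gated by an
  isotope labeling scheme.  In a 1:1 mixture of 15N-only and 13C-only labeled
  chains every observable peak is inter-molecular — the signature used to
  detect inter-molecular beta-sheets and to count the residues in them.

No spin dynamics are simulated: amplitudes are uniform (positional,
empirical simulation), and peaks coinciding within a ppm tolerance are merged
with amplitudes summed and capped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .chemshift import ShiftTable
from .model_io import Structure

__all__ = [
    "AtomRef",
    "Peak2D",
    "PeakList",
    "LabelingScheme",
    "enumerate_cc_peaks",
    "enumerate_nc_peaks",
    "enumerate_pain_peaks",
    "count_sheet_residues",
    "merge_peaks",
]

MERGE_TOL_PPM = 0.01
ALIPHATIC_WINDOW = (0.0, 80.0)  # DARR comparison region, both axes


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_name}{self.residue_number}:{self.atom_name}"


@dataclass(frozen=True)
class Peak2D:
    omega1: float  # ppm
    omega2: float  # ppm
    amplitude: float = 1.0
    atoms: tuple[AtomRef, ...] = ()
    distance: float = 0.0  # Å
    molecularity: str = "intra_chain"  # intra_chain | inter_chain
    residue_relation: str = "intra_residue"  # intra_residue | inter_residue | diagonal
    # every (atom pair, molecularity) merged into this peak; populated by
    # merge_peaks so residue counting survives coincident-shift merging
    contributors: tuple = ()

    def contributor_pairs(self):
        return self.contributors if self.contributors else ((self.atoms, self.molecularity),)


@dataclass
class PeakList:
    peaks: list[Peak2D]
    skipped: int = 0  # atoms/pairs dropped for missing shifts
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def positions(self) -> np.ndarray:
        return np.array([(p.omega1, p.omega2) for p in self.peaks]).reshape(-1, 2)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "omega1_ppm\tomega2_ppm\tamplitude\tatom1\tatom2\tdistance_A\t"
                "molecularity\trelation\n"
            )
            for p in self.peaks:
                a1 = str(p.atoms[0]) if p.atoms else ""
                a2 = str(p.atoms[1]) if len(p.atoms) > 1 else a1
                fh.write(
                    f"{p.omega1:.4f}\t{p.omega2:.4f}\t{p.amplitude:.4f}\t{a1}\t{a2}\t"
                    f"{p.distance:.3f}\t{p.molecularity}\t{p.residue_relation}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PeakList":
        peaks = []
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            f = line.split("\t")
            refs = []
            for tok in (f[3], f[4]):
                if tok:
                    chain, resat, atom = tok.split(":")
                    name, num = resat[:3], int(resat[3:])
                    refs.append(AtomRef(chain, num, name, atom))
            peaks.append(
                Peak2D(
                    omega1=float(f[0]), omega2=float(f[1]), amplitude=float(f[2]),
                    atoms=tuple(refs), distance=float(f[5]),
                    molecularity=f[6], residue_relation=f[7],
                )
            )
        return cls(peaks=peaks)


@dataclass
class LabelingScheme:
    """Isotopes carried by each chain, e.g. ``{"A": {"N15"}, "B": {"C13"}}``."""

    chains: Mapping[str, frozenset[str] | set[str]]

    def isotopes(self, chain_id: str) -> set[str]:
        try:
            return set(self.chains[chain_id])
        except KeyError as exc:
            raise ValueError(f"chain {chain_id!r} has no labeling entry") from exc

    @classmethod
    def uniform(cls, chain_ids: Iterable[str], isotopes: set[str] = frozenset({"C13", "N15"})) -> "LabelingScheme":
        return cls(chains={c: set(isotopes) for c in chain_ids})

    @classmethod
    def mixed(cls, chain_ids: Iterable[str]) -> "LabelingScheme":
        """Alternate chains between 15N-only and 13C-only (1:1 co-fibrillized mix)."""
        chain_ids = list(chain_ids)
        return cls(
            chains={
                c: ({"N15"} if i % 2 == 0 else {"C13"})
                for i, c in enumerate(chain_ids)
            }
        )


def _ref(a) -> AtomRef:
    return AtomRef(a.chain_id, a.residue_number, a.residue_name, a.atom_name)


def merge_peaks(peaks: list[Peak2D], tol_ppm: float = MERGE_TOL_PPM, cap: float = 1.0) -> list[Peak2D]:
    """Merge peaks coinciding within ``tol_ppm`` on both axes.

    Amplitudes are summed and capped so rendered peak heights stay
    comparable; the first contributing peak supplies position/provenance.
    Inter-chain character wins over intra-chain in the merged record (the
    merged peak then reports a genuinely inter-molecular contact).
    """
    buckets: dict[tuple[int, int], Peak2D] = {}
    for p in peaks:
        key = (round(p.omega1 / tol_ppm), round(p.omega2 / tol_ppm))
        if key in buckets:
            q = buckets[key]
            buckets[key] = Peak2D(
                omega1=q.omega1,
                omega2=q.omega2,
                amplitude=min(q.amplitude + p.amplitude, cap),
                atoms=q.atoms,
                distance=min(q.distance, p.distance),
                molecularity="inter_chain" if "inter_chain" in (q.molecularity, p.molecularity) else q.molecularity,
                residue_relation=q.residue_relation,
                contributors=q.contributor_pairs() + p.contributor_pairs(),
            )
        else:
            buckets[key] = p
    return list(buckets.values())


def _source_mask(model: Structure, atoms: list, central_only: bool) -> np.ndarray:
    central = set(model.metadata.get("central_chains") or [])
    if central_only and central:
        return np.array([a.chain_id in central for a in atoms])
    return np.ones(len(atoms), dtype=bool)


def enumerate_cc_peaks(
    model: Structure,
    shifts: ShiftTable,
    cutoff: float = 5.0,
    filter: str = "all",
    include_diagonal: bool = True,
    central_only: bool = True,
    merge_tol_ppm: float = MERGE_TOL_PPM,
) -> PeakList:
    """Enumerate 13C-13C correlation peaks within a distance cutoff.

    For every qualifying carbon pair both orders (delta_i, delta_j) and
    (delta_j, delta_i) are emitted, so the list is symmetric about the
    diagonal.  In stacked models with a recorded central layer, only pairs
    involving at least one central-layer atom are enumerated
    (``central_only=True``); set it to False for all-vs-all.

    ``filter``: ``all`` | ``intra_residue_only`` | ``inter_residue_only``
    (intra-residue means same chain *and* same residue number).
    """
    if filter not in {"all", "intra_residue_only", "inter_residue_only"}:
        raise ValueError(f"unknown filter {filter!r}")
    carbons = [
        a
        for a in model.atoms
        if a.element == "C" or (not a.element and a.atom_name.startswith("C"))
    ]
    skipped = 0
    shifted, deltas = [], []
    for a in carbons:
        d = shifts.get(a.residue_number, a.atom_name)
        if d is None:
            skipped += 1
            continue
        shifted.append(a)
        deltas.append(d)
    peaks: list[Peak2D] = []
    src = _source_mask(model, shifted, central_only)
    if include_diagonal:
        for a, d, is_src in zip(shifted, deltas, src):
            if is_src:
                peaks.append(
                    Peak2D(d, d, 1.0, (_ref(a), _ref(a)), 0.0, "intra_chain", "diagonal")
                )
    if shifted:
        xyz = np.array([a.xyz for a in shifted])
        tree = cKDTree(xyz)
        for i, j in tree.query_pairs(cutoff):
            if not (src[i] or src[j]):
                continue
            ai, aj = shifted[i], shifted[j]
            same_chain = ai.chain_id == aj.chain_id
            intra_res = same_chain and ai.residue_number == aj.residue_number
            if filter == "intra_residue_only" and not intra_res:
                continue
            if filter == "inter_residue_only" and intra_res:
                continue
            dist = float(np.linalg.norm(xyz[i] - xyz[j]))
            mol = "intra_chain" if same_chain else "inter_chain"
            rel = "intra_residue" if intra_res else "inter_residue"
            peaks.append(Peak2D(deltas[i], deltas[j], 1.0, (_ref(ai), _ref(aj)), dist, mol, rel))
            peaks.append(Peak2D(deltas[j], deltas[i], 1.0, (_ref(aj), _ref(ai)), dist, mol, rel))
    merged = merge_peaks(peaks, merge_tol_ppm)
    return PeakList(peaks=merged, skipped=skipped, meta={"cutoff": cutoff, "filter": filter})


def enumerate_nc_peaks(model: Structure, shifts: ShiftTable, mode: str = "NCA") -> PeakList:
    """One bond-mediated N(i)-CA(i) or N(i)-CB(i) peak per residue.

    Glycine has no CB and is skipped in NCB mode; residues missing either
    shift are counted in ``skipped``.
    """
    if mode not in {"NCA", "NCB"}:
        raise ValueError(f"unknown mode {mode!r}")
    target = "CA" if mode == "NCA" else "CB"
    peaks: list[Peak2D] = []
    skipped = 0
    residues: dict[tuple[str, int], dict[str, object]] = {}
    for a in model.atoms:
        if a.atom_name in {"N", target}:
            residues.setdefault((a.chain_id, a.residue_number), {})[a.atom_name] = a
    for (chain, num), d in sorted(residues.items()):
        n_atom, c_atom = d.get("N"), d.get(target)
        if c_atom is None:
            if mode == "NCB" and n_atom is not None and n_atom.residue_name == "GLY":
                continue  # Gly: no CB by construction, not an error
            skipped += 1
            continue
        if n_atom is None:
            skipped += 1
            continue
        dn = shifts.get(num, "N")
        dc = shifts.get(num, target)
        if dn is None or dc is None:
            skipped += 1
            continue
        dist = float(np.linalg.norm(np.subtract(n_atom.xyz, c_atom.xyz)))
        peaks.append(
            Peak2D(dn, dc, 1.0, (_ref(n_atom), _ref(c_atom)), dist, "intra_chain", "intra_residue")
        )
    merged = merge_peaks(peaks)
    return PeakList(peaks=merged, skipped=skipped, meta={"mode": mode})


def enumerate_pain_peaks(
    model: Structure,
    shifts: ShiftTable,
    labeling: LabelingScheme,
    cutoff: float = 5.0,
    merge_tol_ppm: float = MERGE_TOL_PPM,
) -> PeakList:
    """Through-space 15N-13C peaks gated by the isotope labeling scheme.

    A peak requires an N atom on a chain carrying 15N and a C atom on a chain
    carrying 13C within the cutoff.  Under a 1:1 mixed labeling scheme this
    yields inter-chain peaks only; under uniform double labeling both
    molecularities appear.
    """
    for c in model.chain_ids:
        labeling.isotopes(c)  # raises if any chain lacks an entry
    n_atoms = [a for a in model.atoms if a.element == "N" or (not a.element and a.atom_name.startswith("N"))]
    c_atoms = [a for a in model.atoms if a.element == "C" or (not a.element and a.atom_name.startswith("C"))]
    n_atoms = [a for a in n_atoms if "N15" in labeling.isotopes(a.chain_id)]
    c_atoms = [a for a in c_atoms if "C13" in labeling.isotopes(a.chain_id)]
    peaks: list[Peak2D] = []
    skipped = 0
    if n_atoms and c_atoms:
        n_xyz = np.array([a.xyz for a in n_atoms])
        c_xyz = np.array([a.xyz for a in c_atoms])
        pairs = cKDTree(n_xyz).query_ball_tree(cKDTree(c_xyz), cutoff)
        for i, js in enumerate(pairs):
            an = n_atoms[i]
            dn = shifts.get(an.residue_number, an.atom_name)
            for j in js:
                ac = c_atoms[j]
                if an.chain_id == ac.chain_id and an.residue_number == ac.residue_number and an.atom_name == ac.atom_name:
                    continue
                dc = shifts.get(ac.residue_number, ac.atom_name)
                if dn is None or dc is None:
                    skipped += 1
                    continue
                dist = float(np.linalg.norm(n_xyz[i] - c_xyz[j]))
                mol = "intra_chain" if an.chain_id == ac.chain_id else "inter_chain"
                rel = (
                    "intra_residue"
                    if an.chain_id == ac.chain_id and an.residue_number == ac.residue_number
                    else "inter_residue"
                )
                peaks.append(Peak2D(dn, dc, 1.0, (_ref(an), _ref(ac)), dist, mol, rel))
    merged = merge_peaks(peaks, merge_tol_ppm)
    return PeakList(peaks=merged, skipped=skipped, meta={"cutoff": cutoff})


def count_sheet_residues(p: PeakList) -> int:
    """Residues contributing an inter-chain N(i)-CA(i) peak.

    This is the counting argument used to size an inter-molecular beta-sheet
    from a mixed-labeling 15N-13C spectrum: each strand residue of an
    in-register sheet puts its amide N within ~5 Å of the same residue's CA
    on the neighbouring molecule.
    """
    residues = set()
    for peak in p.peaks:
        for pair, molecularity in peak.contributor_pairs():
            if molecularity != "inter_chain" or len(pair) < 2:
                continue
            a_n, a_c = pair
            if (
                a_n.atom_name == "N"
                and a_c.atom_name == "CA"
                and a_n.residue_number == a_c.residue_number
            ):
                residues.add(a_n.residue_number)
    return len(residues)
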