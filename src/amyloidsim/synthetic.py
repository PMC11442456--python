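"""Synthetic ground-truth generators for every pipeline stage.

Everything the pipeline consumes can be generated here with known truth:
idealized alpha-helices and in-register cross-beta stacks (reduced backbone
atom set N, CA, CB, C, O), shift tables via the empirical predictor,
pseudo-experimental 2D spectra (chimera sum + grid noise), exponential
spin-echo decays, and 2D worm-like-chain contour ensembles.  Every stochastic
generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import numpy as np

from . import chemshift, peaksim, spectra
from .model_io import Atom, FibrilGeometry, Structure, build_fibril_stack
from .relaxometry import RelaxationDecay
from .wormlike import Contour

__all__ = [
    "build_backbone",
    "generate_helix",
    "generate_beta_stack",
    "generate_pseudo_experimental_spectrum",
    "generate_decay",
    "generate_wlc_ensemble",
    "CHIMERA_DEMO_SEQUENCE",
    "chimera_demo_models",
]

# Demonstration sequence for the chimera model-selection pipeline: 60 residues
# with an Ala-rich central region (21-40) that forms the inter-molecular
# beta-core, flanked by helical segments (1-20, 41-60) standing in for the
# preserved native helical sub-domain.
CHIMERA_DEMO_SEQUENCE = (
    "KELAQVLKSMGERLAQHWTN"  # 1-20  helical flank
    "AGAVSALTAKAGELAVAQAL"  # 21-40 Ala-rich strand core
    "NTQDLIKEMRSHWGELVKQF"  # 41-60 helical flank
)

# backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_C_CA_CB = 120.5, 110.5
OMEGA = 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from A-B-C with given C-D bond, B-C-D angle, A-B-C-D torsion."""
    # torsion negated so the realized a-b-c-d dihedral matches the IUPAC sign
    ang, tor = np.deg2rad(angle_deg), -np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor), bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(
    sequence: str,
    phi: float,
    psi: float,
    chain_id: str = "A",
    first_residue: int = 1,
    with_cb: bool = True,
) -> Structure:
    """Build a uniform-dihedral backbone (reduced atom set N, CA, C, O [, CB])."""
    n_res = len(sequence)
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    seq3 = [chemshift.ONE_TO_THREE[c] for c in sequence.upper()]
    coords: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        if i == 0:
            N = np.zeros(3)
            CA = np.array([_B_N_CA, 0.0, 0.0])
            ang = np.deg2rad(_A_N_CA_C)
            C = CA + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev = coords[-1]
            N = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
            CA = _place(prev["CA"], prev["C"], N, _B_N_CA, _A_C_N_CA, OMEGA)
            C = _place(prev["C"], N, CA, _B_CA_C, _A_N_CA_C, phi)
        coords.append({"N": N, "CA": CA, "C": C})
    atoms: list[Atom] = []
    for i, (res3, bb) in enumerate(zip(seq3, coords)):
        num = first_residue + i
        O = _place(bb["N"], bb["CA"], bb["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        for name, pos in (("N", bb["N"]), ("CA", bb["CA"]), ("C", bb["C"]), ("O", O)):
            atoms.append(Atom(chain_id, num, res3, name, name[0], tuple(pos)))
        if with_cb and res3 != "GLY":
            CB = _place(bb["N"], bb["C"], bb["CA"], _B_CA_CB, _A_C_CA_CB, 122.5)
            atoms.append(Atom(chain_id, num, res3, "CB", "C", tuple(CB)))
    return Structure(atoms=atoms, model_label=f"backbone_{chain_id}")


def _align_axis_to_x(s: Structure) -> Structure:
    """Rotate so the CA end-to-end vector lies along +x, centered at origin."""
    ca = np.array([a.xyz for a in s.atoms if a.atom_name == "CA"])
    v = ca[-1] - ca[0]
    v /= np.linalg.norm(v)
    # rotation taking v to ex via Rodrigues
    ex = np.array([1.0, 0.0, 0.0])
    axis = np.cross(v, ex)
    sin = np.linalg.norm(axis)
    cos = float(v @ ex)
    if sin < 1e-12:
        R = np.eye(3) if cos > 0 else np.diag([-1.0, -1.0, 1.0])
    else:
        k = axis / sin
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + sin * K + (1 - cos) * (K @ K)
    center = ca.mean(axis=0)
    atoms = []
    for a in s.atoms:
        p = R @ (np.array(a.xyz) - center)
        atoms.append(Atom(a.chain_id, a.residue_number, a.residue_name, a.atom_name, a.element, tuple(p)))
    return Structure(atoms=atoms, model_label=s.model_label, metadata=dict(s.metadata))


def generate_helix(
    n_residues: int | None = None,
    sequence: str | None = None,
    chain_id: str = "A",
    first_residue: int = 1,
) -> Structure:
    """Ideal alpha-helix backbone (phi=-57, psi=-47; ~1.5 Å rise per residue)."""
    if sequence is None:
        if n_residues is None:
            raise ValueError("give n_residues or sequence")
        sequence = "A" * n_residues
    if n_residues is not None and n_residues != len(sequence):
        raise ValueError("n_residues disagrees with sequence length")
    if len(sequence) < 4:
        raise ValueError("a helix needs at least 4 residues")
    s = build_backbone(sequence, phi=-57.0, psi=-47.0, chain_id=chain_id, first_residue=first_residue)
    s.model_label = "ideal_helix"
    return s


def generate_beta_stack(
    strand_sequence: str,
    n_layers: int,
    rise: float = 4.7,
    twist: float = 0.0,
    registry: str = "in_register_parallel",
    first_residue: int = 1,
) -> Structure:
    """In-register cross-beta stack: extended strands stacked along +z.

    The strand (phi=-120, psi=+120) is aligned with its long axis along x so
    that successive layers are pure z-translations: the same-atom inter-layer
    distance equals the rise exactly for the untwisted parallel stack.
    ``registry="antiparallel"`` flips every other layer 180 degrees about the
    strand axis before stacking.
    """
    if registry not in {"in_register_parallel", "antiparallel"}:
        raise ValueError(f"unknown registry {registry!r}")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    strand = _align_axis_to_x(
        build_backbone(strand_sequence, phi=-120.0, psi=120.0, chain_id="A", first_residue=first_residue)
    )
    stack = build_fibril_stack(strand, FibrilGeometry(rise_per_layer=rise, twist_per_layer=twist, n_layers=n_layers))
    if registry == "antiparallel":
        atoms = []
        for a in stack.atoms:
            layer = int(a.chain_id[1:])
            if layer % 2 == 1:  # 180 deg about x: (y, z) -> (-y, -z), then restore layer z
                x, y, z = a.xyz
                z0 = z - layer * rise
                atoms.append(
                    Atom(a.chain_id, a.residue_number, a.residue_name, a.atom_name, a.element, (x, -y, -z0 + layer * rise))
                )
            else:
                atoms.append(a)
        stack = Structure(atoms=atoms, model_label=stack.model_label + "_anti", metadata=dict(stack.metadata))
    return stack


def generate_pseudo_experimental_spectrum(
    native_part: Structure,
    fibril_part: Structure,
    shifts_native: chemshift.ShiftTable,
    shifts_fibril: chemshift.ShiftTable,
    axis1: spectra.Axis,
    axis2: spectra.Axis,
    fwhm_hz: float = 750.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    cutoff: float = 5.0,
    cfg: spectra.SpectrometerConfig | None = None,
) -> spectra.Spectrum2D:
    """Stand-in for a measured reversible-fibril 2D CC spectrum.

    Renders the two parts' distance-cutoff CC peak lists separately, sums the
    spectra (the chimera hypothesis), and adds seeded i.i.d. Gaussian grid
    noise of standard deviation ``noise_sd`` (in units of unit peak height).
    The parts must claim disjoint residue numbers.
    """
    overlap = set(native_part.residue_numbers) & set(fibril_part.residue_numbers)
    if overlap:
        raise ValueError(f"parts share residue numbers {sorted(overlap)[:5]}...")
    cfg = cfg or spectra.SpectrometerConfig()
    parts = []
    for part, table, label in (
        (native_part, shifts_native, "native-part"),
        (fibril_part, shifts_fibril, "fibril-part"),
    ):
        peaks = peaksim.enumerate_cc_peaks(part, table, cutoff=cutoff)
        parts.append(
            spectra.render_spectrum(peaks, axis1, axis2, (fwhm_hz, fwhm_hz), cfg, provenance=label)
        )
    total = spectra.sum_spectra(parts)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        total.grid = total.grid + rng.normal(0.0, noise_sd, total.grid.shape)
    total.provenance = f"pseudo-experimental({total.provenance}, noise_sd={noise_sd}, seed={seed})"
    return total


def chimera_demo_models(n_layers: int = 5, rise: float = 4.7) -> dict:
    """Structures and shift tables for the chimera model-selection demo.

    Returns the pieces needed to mirror the model-comparison experiment on
    the demonstration sequence: the helical flanks and beta-stack core as
    separate parts (the chimera), plus full-helix and full-stack single-state
    models, each with shifts predicted under its own secondary structure.
    """
    from .model_io import SecondaryStructureMap, Span

    seq = CHIMERA_DEMO_SEQUENCE
    helix_n = generate_helix(sequence=seq[:20], first_residue=1)
    helix_c = generate_helix(sequence=seq[40:], first_residue=41)
    helix_c = Structure(
        atoms=[Atom("B", a.residue_number, a.residue_name, a.atom_name, a.element, a.xyz) for a in helix_c.atoms],
        model_label="ideal_helix_C",
    )
    native_flanks = Structure(
        atoms=helix_n.atoms + helix_c.atoms, model_label="native-flanks"
    )
    core = generate_beta_stack(seq[20:40], n_layers=n_layers, rise=rise, first_residue=21)

    native_full = generate_helix(sequence=seq, first_residue=1)
    fibril_full = generate_beta_stack(seq, n_layers=n_layers, rise=rise, first_residue=1)

    helix_map = SecondaryStructureMap([Span(1, 60, "helix", "all-helix")])
    strand_map = SecondaryStructureMap([Span(1, 60, "strand", "all-strand")])
    chimera_map = SecondaryStructureMap(
        [Span(1, 20, "helix", "flankN"), Span(21, 40, "strand", "core"), Span(41, 60, "helix", "flankC")]
    )
    return {
        "sequence": seq,
        "native_flanks": native_flanks,
        "core_stack": core,
        "native_full": native_full,
        "fibril_full": fibril_full,
        "shifts_helix": chemshift.predict_shifts(seq, helix_map),
        "shifts_strand": chemshift.predict_shifts(seq, strand_map),
        "shifts_chimera": chemshift.predict_shifts(seq, chimera_map),
    }


def generate_decay(
    t2_ms: float,
    delays_ms,
    noise_frac: float = 0.0,
    seed: int = 0,
    i0: float = 10.0,
    temperature_C: float | None = None,
) -> RelaxationDecay:
    """Exponential spin-echo decay with multiplicative Gaussian noise."""
    if t2_ms <= 0 or i0 <= 0:
        raise ValueError("T2' and I0 must be > 0")
    delays = np.asarray(list(delays_ms), dtype=float)
    ideal = i0 * np.exp(-delays / t2_ms)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        ideal = ideal * (1.0 + rng.normal(0.0, noise_frac, ideal.shape))
        ideal = np.maximum(ideal, 1e-12)
    return RelaxationDecay(delays, ideal, temperature_C=temperature_C)


def generate_wlc_ensemble(
    lp_nm: float,
    contour_length_nm: float,
    step_nm: float,
    n_chains: int,
    seed: int = 0,
) -> list[Contour]:
    """2D worm-like chains with tangent correlation exp(-s / (2 Lp)).

    Each chain takes steps of fixed length with Gaussian turning angles of
    variance step/Lp (the 2D surface-equilibrated convention); the initial
    direction is uniform.
    """
    if min(lp_nm, contour_length_nm, step_nm) <= 0 or n_chains < 1:
        raise ValueError("parameters must be positive")
    n_steps = int(round(contour_length_nm / step_nm))
    if n_steps < 2:
        raise ValueError("contour shorter than 2 steps")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_chains):
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        turns = rng.normal(0.0, np.sqrt(step_nm / lp_nm), n_steps - 1)
        angles = theta0 + np.concatenate([[0.0], np.cumsum(turns)])
        steps = step_nm * np.column_stack([np.cos(angles), np.sin(angles)])
        pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        out.append(Contour(pts, arc_step=step_nm, source_label=f"wlc{i}"))
    return out
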