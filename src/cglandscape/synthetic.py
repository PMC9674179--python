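"""Synthetic fixtures: receptors, ensembles, umbrella oracles, reference
complexes and scan sequences.

Everything the pipeline consumes can be generated here, deterministically
from a seed, with machine-readable ground truth attached.  The synthetic
receptor is a two-lobe hinge protein: two compact 40-residue domains on a
3x3xN lattice (3.8 A spacing) joined by a flexible linker, with a 5-nt
single-site RNA ligand posed in the inter-domain cleft of the closed
conformer.  The open conformer is a rigid hinge rotation of the second
domain about the linker.  Pocket-lining faces carry distinct residue types
so a type-pooled residue-base potential binds the ligand only at the cleft.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .free_energy import KB, UmbrellaDataset, UmbrellaWindow
from .structures import AA1_TO_3, CGSite, CGStructure, Ensemble, PROTEIN, RNA

GRID_SPACING = 3.8          # CA-CA distance, A
LIGAND_SPACING = 5.0        # nucleotide site spacing, A
CLEFT_GAP = 10.0            # inner-face separation of the closed form, A

_FACE1_TYPES = ["ARG", "LYS", "ASN"]
_FACE2_TYPES = ["SER", "THR", "GLN"]
_CORE_TYPES = ["ALA", "LEU", "GLU", "GLY", "VAL", "ASP"]
_LIGAND_SEQ = "ACGUA"


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic world.

    Defaults: two 40-residue domains, 4-residue linker, 5-nt ligand
    (a short RNA of 5 nucleotides matches the modelled target), 50 degree
    hinge opening, 0.5 A thermal-noise sigma for generated ensembles.
    """

    seed: int = 0
    n_residues_per_domain: int = 40
    linker_length: int = 4
    open_angle_deg: float = 50.0
    closed_angle_deg: float = 0.0
    ligand_length: int = 5
    noise_sigma: float = 0.5
    planted_contacts: list = None

    def __post_init__(self):
        if self.open_angle_deg == self.closed_angle_deg:
            raise SyntheticError("open and closed angles must differ")
        if self.n_residues_per_domain < 9:
            raise SyntheticError("domains need at least 9 residues")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _snake_grid(n, spacing=GRID_SPACING):
    """First n points of a 3x3xN lattice in snake order (consecutive
    points adjacent)."""
    pts = []
    k = 0
    while len(pts) < n:
        for j in range(3):
            xs = range(3) if (k + j) % 2 == 0 else range(2, -1, -1)
            row = j if k % 2 == 0 else 2 - j
            for i in xs:
                pts.append((i * spacing, row * spacing, k * spacing))
                if len(pts) == n:
                    return np.array(pts)
        k += 1
    return np.array(pts)


def _arc_points(p1, p2, n, bulge=12.0):
    """n interior points on a path p1->p2 bulged in +y, routing the
    linker over the top of the cleft, clear of the ligand."""
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    t = np.linspace(0, 1, n + 2)[1:-1]
    up = np.array([0.0, 1.0, 0.0])
    return p1 + np.outer(t, p2 - p1) + bulge * np.outer(
        np.sin(np.pi * t), up)


def _rotate_z(points, angle_deg, origin):
    th = np.deg2rad(angle_deg)
    rot = np.array([
        [np.cos(th), -np.sin(th), 0.0],
        [np.sin(th), np.cos(th), 0.0],
        [0.0, 0.0, 1.0],
    ])
    return (points - origin) @ rot.T + origin


def _assign_types(n_dom, face_col, face_types):
    """Residue types for one domain: face column gets face_types, rest
    cycles through the core alphabet."""
    grid = _snake_grid(n_dom)
    types = []
    fc = 0
    cc = 0
    for p in grid:
        if abs(p[0] - face_col) < 1e-9:
            types.append(face_types[fc % len(face_types)])
            fc += 1
        else:
            types.append(_CORE_TYPES[cc % len(_CORE_TYPES)])
            cc += 1
    return types


def _build_receptor_coords(spec, angle_deg):
    """Coordinates of receptor chain A for a given hinge angle, plus the
    (angle-independent) bookkeeping needed for annotations."""
    n = spec.n_residues_per_domain
    d1 = _snake_grid(n)
    d2_closed = _snake_grid(n) + np.array([2 * GRID_SPACING + CLEFT_GAP,
                                           0.0, 0.0])
    p1 = d1[-1]
    p2 = d2_closed[0]
    # hinge at domain 2's linker-attachment corner; the negative sense
    # swings the whole domain away from the cleft (book-opening motion)
    d2 = _rotate_z(d2_closed, -angle_deg, p2)
    p2r = d2[0]
    link = _arc_points(p1, p2r, spec.linker_length)
    return np.vstack([d1, link, d2]), d1, d2_closed


def _ligand_coords(spec, pocket_center):
    m = spec.ligand_length
    z = (np.arange(m) - (m - 1) / 2.0) * LIGAND_SPACING
    coords = np.tile(pocket_center, (m, 1))
    coords[:, 2] += z
    return coords


def make_two_domain_receptor(spec=None):
    """Open and closed conformers of the hinge receptor plus its ligand.

    Returns (open_structure, closed_structure) sharing one topology:
    chain A = two-domain protein with linker, chain B = RNA ligand posed
    in the cleft of the closed form (same pose in both conformers).
    Annotations: domain1, domain2, linker, pocket (both cleft faces),
    sim (a surface segment of domain 1), znf_patch (a segment of
    domain 2).
    """
    spec = spec or SyntheticSpec()
    n = spec.n_residues_per_domain
    coords_closed, d1, d2c = _build_receptor_coords(
        spec, spec.closed_angle_deg)
    coords_open, _, _ = _build_receptor_coords(spec, spec.open_angle_deg)

    inner1 = 2 * GRID_SPACING
    inner2 = 2 * GRID_SPACING + CLEFT_GAP
    types = (_assign_types(n, inner1, _FACE1_TYPES)
             + ["GLY"] * spec.linker_length
             + _assign_types(n, 0.0, _FACE2_TYPES))
    # face columns of domain 2: its x=0 column sits at inner2 after shift
    face1_idx = np.nonzero(np.abs(d1[:, 0] - inner1) < 1e-9)[0]
    face2_idx = np.nonzero(np.abs(d2c[:, 0] - inner2) < 1e-9)[0] \
        + n + spec.linker_length

    pocket_sites = np.concatenate([face1_idx, face2_idx])
    pocket_center = np.vstack([d1[face1_idx],
                               d2c[face2_idx - n - spec.linker_length]
                               ]).mean(axis=0)
    lig = _ligand_coords(spec, pocket_center)

    seq = _LIGAND_SEQ * (spec.ligand_length // len(_LIGAND_SEQ) + 1)

    def build(coords):
        sites = [
            CGSite("A", i + 1, types[i], PROTEIN, coords[i])
            for i in range(len(coords))
        ] + [
            CGSite("B", j + 1, seq[j], RNA, lig[j])
            for j in range(spec.ligand_length)
        ]
        s = CGStructure(sites)
        if _min_distance(s.coords) < 1.0:
            raise SyntheticError("degenerate geometry: overlapping sites")
        s.annotate("domain1", ("A", 1, n))
        s.annotate("linker", ("A", n + 1, n + spec.linker_length))
        s.annotate("domain2", ("A", n + spec.linker_length + 1,
                               2 * n + spec.linker_length))
        s.annotate("pocket", [("A", int(i) + 1, int(i) + 1)
                              for i in sorted(pocket_sites)])
        # clamp-facing surface patches (y = 0 face, middle heights): the
        # SIM-like patch on domain 1 and the ZnF-like patch on domain 2.
        # Patches span two lattice heights so a clamp anchored to them
        # cannot pivot about a single line.
        face_patch = np.sort(np.nonzero(
            (np.abs(d1[:, 1]) < 1e-9)
            & (d1[:, 2] > 0.5 * GRID_SPACING)
            & (d1[:, 2] < 3.5 * GRID_SPACING))[0])
        off = n + spec.linker_length
        s.annotate("sim", [("A", int(i) + 1, int(i) + 1)
                           for i in face_patch])
        s.annotate("znf_patch", [("A", int(i) + 1 + off, int(i) + 1 + off)
                                 for i in face_patch])
        s.annotate("ligand", ("B", 1, spec.ligand_length))
        return s

    return build(coords_open), build(coords_closed)


def _min_distance(coords):
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return d.min()


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def make_hinge_ensemble(spec, angles, fractions, n_frames, receptor_only=False):
    """Ensemble of noisy conformers at the given hinge angles.

    Frames are drawn independently: a mode is picked with the stated
    fractions, then Gaussian coordinate noise of ``spec.noise_sigma`` is
    added.  Ground-truth mode labels are attached as ``frame_labels``.
    """
    if n_frames < 2:
        raise SyntheticError("need at least 2 frames")
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != len(angles) or abs(fractions.sum() - 1.0) > 1e-9:
        raise SyntheticError("fractions must match angles and sum to 1")
    rng = np.random.default_rng(spec.seed)
    conformers = []
    for ang in angles:
        s = _receptor_at_angle(spec, ang)
        conformers.append(s.coords)
    topo = _receptor_at_angle(spec, angles[0])
    labels = rng.choice(len(angles), size=n_frames, p=fractions)
    frames = np.array([
        conformers[lab] + rng.normal(0.0, spec.noise_sigma,
                                     conformers[lab].shape)
        for lab in labels
    ])
    return Ensemble(topo, frames, frame_labels=labels.tolist())


def _receptor_at_angle(spec, angle):
    import copy
    sub = copy.copy(spec)
    sub = SyntheticSpec(
        seed=spec.seed, n_residues_per_domain=spec.n_residues_per_domain,
        linker_length=spec.linker_length, open_angle_deg=angle + 1e-6,
        closed_angle_deg=angle - 1e-6, ligand_length=spec.ligand_length,
        noise_sigma=spec.noise_sigma,
        planted_contacts=spec.planted_contacts,
    )
    opened, _ = make_two_domain_receptor(sub)
    return opened


def make_bimodal_ensemble(spec, n_frames, mode_fractions=(0.5, 0.5)):
    """Ensemble mixing the open and closed conformers (label 0 = open)."""
    spec = spec or SyntheticSpec()
    return make_hinge_ensemble(
        spec, [spec.open_angle_deg, spec.closed_angle_deg],
        mode_fractions, n_frames,
    )


# ---------------------------------------------------------------------------
# umbrella oracle
# ---------------------------------------------------------------------------

def make_umbrella_oracle(k_true, centers, k_bias, n_samples, T=300.0,
                         seed=0):
    """Umbrella dataset with exactly known free energy F(x) = k_true x^2/2.

    Samples are drawn exactly from the Boltzmann distribution of the
    harmonic potential plus each window's harmonic bias (a Gaussian with
    mean k_bias*c/(k_true+k_bias) and variance kT/(k_true+k_bias)); no
    dynamics is involved, so WHAM correctness is testable on its own.
    """
    if len(centers) < 3:
        raise SyntheticError("need at least 3 windows")
    if k_true <= 0 or k_bias <= 0:
        raise SyntheticError("spring constants must be positive")
    rng = np.random.default_rng(seed)
    kt = KB * T
    windows = []
    for c in centers:
        k_tot = k_true + k_bias
        mean = k_bias * c / k_tot
        sd = np.sqrt(kt / k_tot)
        windows.append(UmbrellaWindow(
            center=float(c), spring_constant=float(k_bias),
            samples=rng.normal(mean, sd, int(n_samples)),
        ))
    return UmbrellaDataset(
        windows=windows, temperature=T, coordinate="x",
        metadata={"k_true": float(k_true), "form": "harmonic"},
    )


# ---------------------------------------------------------------------------
# reference complex with planted atomic contacts
# ---------------------------------------------------------------------------

def _default_planted(structure, spec):
    """One planted contact per ligand base to its nearest pocket residue
    in each domain, alternating counts 4 and 2."""
    lig_idx = structure.annotation_indices("ligand")
    planted = []
    coords = structure.coords
    for b, j in enumerate(lig_idx):
        for dom, count in (("domain1", 4), ("domain2", 2)):
            pocket = [i for i in structure.annotation_indices("pocket")
                      if i in set(structure.annotation_indices(dom))]
            d = np.linalg.norm(coords[pocket] - coords[j], axis=1)
            best = pocket[int(np.argmin(d))]
            planted.append((structure.sites[best].residue_index, b + 1,
                            count))
    return planted


def make_reference_complex(spec=None):
    """Closed receptor/ligand complex with planted residue-base contacts.

    Pseudo heavy atoms realizing the planted atomic-contact counts are
    attached as ``structure.heavy_atoms`` (site index -> (m, 3) array);
    the realized counts are recorded in ``structure.planted_counts``.
    Placement keeps a >=0.4 A margin to the counting cutoff so a 0.01 A
    jitter cannot change any count.
    """
    spec = spec or SyntheticSpec()
    _, closed = make_two_domain_receptor(spec)
    planted = spec.planted_contacts
    if planted is None:
        planted = _default_planted(closed, spec)

    res_lookup = {
        (s.chain_id, s.residue_index): i
        for i, s in enumerate(closed.sites)
    }
    coords = closed.coords
    heavy = {}
    counts = {}
    for res_idx, base_idx, count in planted:
        i = res_lookup.get(("A", res_idx))
        j = res_lookup.get(("B", base_idx))
        if i is None or j is None:
            raise SyntheticError(
                f"planted contact ({res_idx},{base_idx}) names missing sites"
            )
        u = coords[i] - coords[j]
        dist = np.linalg.norm(u)
        if dist < 4.0:
            raise SyntheticError("infeasible planting: sites too close")
        # project the residue direction onto the plane normal to the RNA
        # chain axis so atoms stay >= one base spacing from neighbors
        axis = np.array([0.0, 0.0, 1.0])
        u = u - (u @ axis) * axis
        if np.linalg.norm(u) < 1e-6:
            u = np.array([1.0, 0.0, 0.0])
        u = u / np.linalg.norm(u)
        perp = np.cross(u, axis)
        atoms = []
        for m in range(count):
            ang = 2.0 * np.pi * m / max(count, 1)
            offset = 0.4 * (np.cos(ang) * perp + np.sin(ang) * axis)
            atoms.append(coords[j] + u * (3.1 + 0.1 * m) + offset)
        heavy.setdefault(i, []).extend(atoms)
        counts[(res_idx, base_idx)] = counts.get((res_idx, base_idx), 0) \
            + count
    closed.heavy_atoms = {i: np.array(v) for i, v in heavy.items()}
    closed.planted_counts = counts
    from .potentials import count_atomic_contacts
    realized = count_atomic_contacts(closed)
    if realized != counts:
        raise SyntheticError(
            "infeasible planting: realized atomic contacts "
            f"{realized} differ from requested {counts}"
        )
    return closed


# ---------------------------------------------------------------------------
# SUMO-mimic complex (bivalent clamp)
# ---------------------------------------------------------------------------

def make_sumo_mimic_complex(spec=None, include_ligand=True):
    """Closed receptor plus a SUMO-like clamp chain spanning both domains.

    The clamp (chain S) runs along one face of the closed receptor so that
    its N-terminal segment faces domain 1 (annotation ``beta2``, the
    strand that pairs with the receptor's ``sim`` segment) and its
    C-terminal segment faces domain 2 (annotation ``znf_contact``).
    """
    spec = spec or SyntheticSpec()
    _, closed = make_two_domain_receptor(spec)
    sites = list(closed.sites)
    if not include_ligand:
        sites = [s for s in sites if s.chain_id != "B"]
    # the clamp must behave as a folded domain, not a floppy strand: a
    # triangular-prism fold (three snake rows) gives every site several
    # native contacts, so the bivalent constraint transmits orientation,
    # and its anchor points are non-coplanar with any single pivot line
    row1 = [(2.0 + 3.8 * i, -6.0, 5.7) for i in range(6)]
    row2 = [(21.0 - 3.8 * j, -6.0, 9.5) for j in range(6)]
    row3 = [(2.0 + 3.8 * i, -9.3, 7.6) for i in range(6)]
    clamp_coords = np.array(row1 + row2 + row3)
    n_clamp = len(clamp_coords)
    clamp_types = ["MET" if i % 2 == 0 else "PHE" for i in range(n_clamp)]
    sites = sites + [
        CGSite("S", i + 1, clamp_types[i], PROTEIN, clamp_coords[i])
        for i in range(n_clamp)
    ]
    ann = {k: v for k, v in closed.domain_annotations.items()
           if include_ligand or k != "ligand"}
    s = CGStructure(sites, ann)
    s.annotate("beta2", [("S", 1, 2), ("S", 11, 14)])
    s.annotate("znf_contact", [("S", 5, 8), ("S", 17, 18)])
    return s


def make_sim_template(peptide_types=("VAL", "ILE", "LEU", "VAL", "ILE",
                                     "LEU")):
    """Canonical peptide/partner template for the sequence scan.

    A 6-residue peptide strand (chain P, annotation ``peptide``) paired
    at beta-sheet distance alongside a 10-residue hydrophobic partner
    strand (chain S, annotation ``beta2``), emulating a SIM peptide laid
    against a SUMO beta2 strand.
    """
    n_partner = 10
    partner = [
        CGSite("S", i + 1, "ILE", PROTEIN,
               [0.0, i * GRID_SPACING, 0.0])
        for i in range(n_partner)
    ]
    offset = 2  # peptide registered against partner residues 3..8
    peptide = [
        CGSite("P", j + 1, peptide_types[j], PROTEIN,
               [5.0, (offset + j) * GRID_SPACING, 0.0])
        for j in range(len(peptide_types))
    ]
    s = CGStructure(partner + peptide)
    s.annotate("peptide", ("P", 1, len(peptide_types)))
    s.annotate("beta2", ("S", 3, 8))
    return s


# ---------------------------------------------------------------------------
# scan sequences
# ---------------------------------------------------------------------------

_POLAR = "DEKNQSRGTH"


def make_scan_sequence(window_start, length=11, seed=0, total_length=200,
                       extra_starts=()):
    """Random polar background with hydrophobic window(s) planted.

    The planted window is all-ILE, the residue maximizing the packaged
    hydrophobicity-product scan potential, so an exhaustive scan has its
    global minimum at ``window_start`` (1-based).  ``extra_starts`` plants
    additional identical windows.
    """
    starts = [window_start] + list(extra_starts)
    for st in starts:
        if st < 1 or st + length - 1 > total_length:
            raise SyntheticError("planted window outside sequence")
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list(_POLAR), size=total_length)))
    for st in starts:
        seq[st - 1:st - 1 + length] = "I" * length
    return ("synthetic_scan", "".join(seq))
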