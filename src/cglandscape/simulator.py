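"""Structure-based coarse-grained Langevin simulator with bias potentials.

A desk-scale stand-in for heavyweight coarse-grained force fields: chains
are held by harmonic bonds, native structure by Gaussian contact wells
enumerated from a reference, protein--RNA attraction by the switching-well
residue--base potential, and everything else repels softly below 4 A.
Dynamics is BAOAB Langevin in reduced units (mass 1, energies kcal/mol,
distances A, kB = 0.0019872 kcal/mol/K).

Bias potentials: harmonic umbrella on the RNA--pocket distance R,
harmonic restraint on a (precomputed, alignment-free) PC0 direction,
sheet-registration restraints and the bivalent cross-link tether.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .free_energy import KB, UmbrellaDataset, UmbrellaWindow
from .structures import PROTEIN, RNA


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Force-field arrays built from a reference structure.

    All index arrays are flat site indices into the reference; bonded
    terms come from chain connectivity, native Gaussian wells from pairs
    within ``native_cutoff`` in the reference, residue--base wells from
    the contact potential's type table, and excluded volume from every
    remaining pair.
    """

    reference: object
    bond_idx: np.ndarray
    bond_r0: np.ndarray
    k_bond: float
    nat_idx: np.ndarray
    nat_eps: np.ndarray
    nat_r0: np.ndarray
    nat_width: float
    rb_idx: np.ndarray
    rb_eps: np.ndarray          # normalized eps; multiplied by lam
    lam: float
    contact_range: float
    well_width: float
    ev_idx: np.ndarray
    r_ev: float
    k_ev: float
    params: dict = field(default_factory=dict)

    @property
    def n_sites(self):
        return self.reference.n_sites

    def with_lambda(self, lam):
        import copy
        t = copy.copy(self)
        t.lam = float(lam)
        return t


DEFAULT_PARAMS = dict(
    k_bond=20.0,            # kcal/mol/A^2
    native_cutoff=6.5,      # A, reference distance enumerating contacts
    native_depth=2.5,       # kcal/mol, intra-domain Gaussian well depth
                            # (domains behave as compact folded units)
    interdomain_depth=0.0,  # kcal/mol, inter-domain wells (hinge free)
    native_width=1.0,       # A
    r_ev=4.0,               # A, soft excluded-volume wall
    k_ev=10.0,              # kcal/mol/A^2
)


def build_topology(reference, potential=None, params=None):
    """Enumerate bonded, native, residue--base and excluded-volume terms.

    ``potential`` supplies the residue--base table and switching-well
    geometry (no protein--RNA attraction without it).  Deterministic in
    its inputs.
    """
    import warnings

    p = dict(DEFAULT_PARAMS)
    p.update(params or {})
    sites = reference.sites
    n = reference.n_sites
    coords = reference.coords
    chains = np.array([s.chain_id for s in sites])
    classes = reference.molecule_class_array()

    for cid, entry in reference.chain_table.items():
        lo, hi = entry["span"]
        if hi == lo:
            warnings.warn(f"chain {cid} has a single site")

    bonds = [
        (i, i + 1) for i in range(n - 1) if chains[i] == chains[i + 1]
    ]
    bond_idx = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    bond_r0 = np.array([
        np.linalg.norm(coords[i] - coords[j]) for i, j in bonds
    ])

    dom = np.full(n, -1)
    for k, name in enumerate(("domain1", "domain2")):
        if name in reference.domain_annotations:
            dom[reference.annotation_indices(name)] = k

    dmat = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    nat, nat_eps, nat_r0 = [], [], []
    rb, rb_eps = [], []
    rb_table = potential.residue_base_norm if potential else {}
    for i in range(n):
        for j in range(i + 1, n):
            same_chain = chains[i] == chains[j]
            if same_chain and j - i == 1:
                continue
            pc = {classes[i], classes[j]}
            if pc == {PROTEIN, RNA}:
                res, base = (i, j) if classes[i] == PROTEIN else (j, i)
                eps = rb_table.get(
                    (sites[res].residue_type, sites[base].residue_type),
                    0.0)
                if eps > 0:
                    rb.append((i, j))
                    rb_eps.append(eps)
                continue
            if dmat[i, j] > p["native_cutoff"]:
                continue
            inter_dom = dom[i] >= 0 and dom[j] >= 0 and dom[i] != dom[j]
            depth = p["interdomain_depth"] if (inter_dom or not same_chain) \
                else p["native_depth"]
            if depth > 0:
                nat.append((i, j))
                nat_eps.append(depth)
                nat_r0.append(dmat[i, j])

    # native pairs keep their Gaussian well and are excluded from the
    # repulsive wall (their reference distance may sit inside it)
    excluded = set(map(tuple, bonds)) | set(nat)
    ev = [
        (i, j) for i in range(n) for j in range(i + 1, n)
        if (i, j) not in excluded
    ]
    return Topology(
        reference=reference,
        bond_idx=bond_idx, bond_r0=bond_r0, k_bond=p["k_bond"],
        nat_idx=np.array(nat, dtype=np.int64).reshape(-1, 2),
        nat_eps=np.array(nat_eps), nat_r0=np.array(nat_r0),
        nat_width=p["native_width"],
        rb_idx=np.array(rb, dtype=np.int64).reshape(-1, 2),
        rb_eps=np.array(rb_eps),
        lam=(potential.lam if potential else 1.0),
        contact_range=(potential.contact_range if potential else 6.5),
        well_width=(potential.well_width if potential else 2.0),
        ev_idx=np.array(ev, dtype=np.int64).reshape(-1, 2),
        r_ev=p["r_ev"], k_ev=p["k_ev"],
        params=p,
    )


# ---------------------------------------------------------------------------
# bias potentials
# ---------------------------------------------------------------------------

@dataclass
class BiasPotential:
    """One bias term.

    kinds: 'harmonic_R' (params: pocket_idx, ligand_idx, center, k),
    'harmonic_PC0' (params: scope_idx, vector (m,3), mean (m,3), center,
    k; alignment-free linear CV), 'sheet_pairs' and 'crosslink_tether'
    (params: pairs (m,2), r0 (m,), k).
    """

    kind: str
    params: dict

    def __post_init__(self):
        if self.kind not in ("harmonic_R", "harmonic_PC0", "sheet_pairs",
                            "crosslink_tether"):
            raise ValueError(f"unknown bias kind {self.kind!r}")
        k = self.params.get("k", 0.0)
        if np.any(np.asarray(k) < 0):
            raise ValueError("bias spring constants must be >= 0")


def harmonic_r_bias(topology_or_structure, center, k,
                    pocket_annotation="pocket", ligand_chain="B"):
    ref = getattr(topology_or_structure, "reference", topology_or_structure)
    return BiasPotential("harmonic_R", dict(
        pocket_idx=ref.annotation_indices(pocket_annotation),
        ligand_idx=ref.chain_indices(ligand_chain),
        center=float(center), k=float(k),
    ))


@dataclass
class RelaxProtocol:
    """Two-phase protocol: biased guiding phase, then unbiased relax."""

    phases: list  # list of (name, list_of_biases)


def make_sumo_biases(complex_structure, sim_annotation="sim",
                     beta2_annotation="beta2",
                     znf_annotation="znf_patch",
                     clamp_tail_annotation="znf_contact",
                     params=None):
    """Sheet-registration bias and bivalent cross-link tether.

    The sheet bias pairs the receptor's SIM segment with the clamp's
    beta2 strand residue-by-residue in register (weak springs toward the
    beta-pairing distance).  The tether restrains the clamp to both of
    its receptor anchor surfaces — the SIM-bearing domain and the
    ZnF-like domain — at their current distances, realizing the bivalent
    constraint.  Returns (biases, RelaxProtocol).
    """
    p = dict(sheet_k=0.5, sheet_r0=5.0, tether_k=5.0, tether_n_anchor=3)
    p.update(params or {})
    s = complex_structure
    sim_idx = s.annotation_indices(sim_annotation)
    beta2_idx = s.annotation_indices(beta2_annotation)
    znf_idx = s.annotation_indices(znf_annotation)
    tail_idx = s.annotation_indices(clamp_tail_annotation)
    for a, b in ((set(sim_idx), set(beta2_idx)),
                 (set(znf_idx), set(tail_idx)),
                 (set(sim_idx), set(znf_idx))):
        if a & b:
            raise ValueError("bias annotations overlap")
    coords = s.coords

    m = min(len(sim_idx), len(beta2_idx))
    sheet_pairs = np.stack([sim_idx[:m], beta2_idx[:m]], axis=1)
    sheet = BiasPotential("sheet_pairs", dict(
        pairs=sheet_pairs,
        r0=np.full(m, p["sheet_r0"]),
        k=float(p["sheet_k"]),
    ))

    def nearest_pairs(clamp_sites, anchor_sites):
        # several anchors per clamp site: single point-to-point distances
        # leave rotations about the anchor points unconstrained
        n_anchor = min(int(p["tether_n_anchor"]), len(anchor_sites))
        pairs, r0 = [], []
        for i in clamp_sites:
            d = np.linalg.norm(coords[anchor_sites] - coords[i], axis=1)
            for idx in np.argsort(d)[:n_anchor]:
                pairs.append((i, int(anchor_sites[idx])))
                r0.append(float(d[idx]))
        return pairs, r0

    p1, r1 = nearest_pairs(beta2_idx, sim_idx)
    p2, r2 = nearest_pairs(tail_idx, znf_idx)
    tether = BiasPotential("crosslink_tether", dict(
        pairs=np.array(p1 + p2, dtype=np.int64),
        r0=np.array(r1 + r2),
        k=float(p["tether_k"]),
    ))
    protocol = RelaxProtocol(phases=[
        ("bias", [sheet, tether]),
        ("relax", []),
    ])
    return [sheet, tether], protocol


def _pack_biases(biases, n_sites):
    """Flatten bias list into kernel arrays."""
    rest_pairs, rest_r0, rest_k = [], [], []
    poc = lig = np.zeros(0, dtype=np.int64)
    k_r = 0.0
    c_r = 0.0
    pc0_scope = np.zeros(0, dtype=np.int64)
    pc0_vec = np.zeros((0, 3))
    pc0_mean = np.zeros((0, 3))
    k_pc0 = 0.0
    c_pc0 = 0.0
    for b in biases or []:
        if b.kind in ("sheet_pairs", "crosslink_tether"):
            pairs = np.asarray(b.params["pairs"], dtype=np.int64)
            rest_pairs.append(pairs)
            rest_r0.append(np.asarray(b.params["r0"], dtype=float))
            rest_k.append(np.full(len(pairs), float(b.params["k"])))
        elif b.kind == "harmonic_R":
            if k_r:
                raise ValueError("only one harmonic_R bias supported")
            poc = np.asarray(b.params["pocket_idx"], dtype=np.int64)
            lig = np.asarray(b.params["ligand_idx"], dtype=np.int64)
            k_r = float(b.params["k"])
            c_r = float(b.params["center"])
        elif b.kind == "harmonic_PC0":
            if k_pc0:
                raise ValueError("only one harmonic_PC0 bias supported")
            pc0_scope = np.asarray(b.params["scope_idx"], dtype=np.int64)
            pc0_vec = np.asarray(b.params["vector"], dtype=float)
            pc0_mean = np.asarray(b.params["mean"], dtype=float)
            k_pc0 = float(b.params["k"])
            c_pc0 = float(b.params["center"])
    if rest_pairs:
        rp = np.vstack(rest_pairs)
        rr = np.concatenate(rest_r0)
        rk = np.concatenate(rest_k)
    else:
        rp = np.zeros((0, 2), dtype=np.int64)
        rr = np.zeros(0)
        rk = np.zeros(0)
    return rp, rr, rk, poc, lig, k_r, c_r, pc0_scope, pc0_vec, pc0_mean, \
        k_pc0, c_pc0


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _forces(x, f,
            bond_idx, bond_r0, k_bond,
            nat_idx, nat_eps, nat_r0, nat_w,
            rb_idx, rb_eps, lam, rc, wsw,
            ev_idx, r_ev, k_ev,
            rest_idx, rest_r0, rest_k,
            poc_idx, lig_idx, k_r, c_r,
            pc0_scope, pc0_vec, pc0_mean, k_pc0, c_pc0):
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    energy = 0.0
    # bonds
    for b in range(bond_idx.shape[0]):
        i, j = bond_idx[b, 0], bond_idx[b, 1]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dr = r - bond_r0[b]
        energy += 0.5 * k_bond * dr * dr
        mag = -k_bond * dr / r
        f[i, 0] += mag * dx0
        f[i, 1] += mag * dx1
        f[i, 2] += mag * dx2
        f[j, 0] -= mag * dx0
        f[j, 1] -= mag * dx1
        f[j, 2] -= mag * dx2
    # native Gaussian wells
    inv_w2 = 1.0 / (nat_w * nat_w)
    for c in range(nat_idx.shape[0]):
        i, j = nat_idx[c, 0], nat_idx[c, 1]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dr = r - nat_r0[c]
        if dr * dr * inv_w2 > 36.0:
            continue
        g = np.exp(-0.5 * dr * dr * inv_w2)
        energy += -nat_eps[c] * g
        mag = -nat_eps[c] * g * dr * inv_w2 / r
        f[i, 0] += mag * dx0
        f[i, 1] += mag * dx1
        f[i, 2] += mag * dx2
        f[j, 0] -= mag * dx0
        f[j, 1] -= mag * dx1
        f[j, 2] -= mag * dx2
    # residue-base switching wells
    rmax = rc + wsw
    for c in range(rb_idx.shape[0]):
        i, j = rb_idx[c, 0], rb_idx[c, 1]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        if r2 >= rmax * rmax:
            continue
        r = np.sqrt(r2)
        eps = lam * rb_eps[c]
        if r <= rc:
            energy += -eps
        else:
            t = np.pi * (r - rc) / wsw
            s = 0.5 * (1.0 + np.cos(t))
            energy += -eps * s
            dsdr = -0.5 * np.pi / wsw * np.sin(t)
            mag = eps * dsdr / r
            f[i, 0] += mag * dx0
            f[i, 1] += mag * dx1
            f[i, 2] += mag * dx2
            f[j, 0] -= mag * dx0
            f[j, 1] -= mag * dx1
            f[j, 2] -= mag * dx2
    # soft excluded volume
    for c in range(ev_idx.shape[0]):
        i, j = ev_idx[c, 0], ev_idx[c, 1]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        if r2 >= r_ev * r_ev:
            continue
        r = np.sqrt(r2)
        dr = r - r_ev
        energy += 0.5 * k_ev * dr * dr
        mag = -k_ev * dr / r
        f[i, 0] += mag * dx0
        f[i, 1] += mag * dx1
        f[i, 2] += mag * dx2
        f[j, 0] -= mag * dx0
        f[j, 1] -= mag * dx1
        f[j, 2] -= mag * dx2
    # harmonic restraints (sheet / tether)
    for c in range(rest_idx.shape[0]):
        i, j = rest_idx[c, 0], rest_idx[c, 1]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dr = r - rest_r0[c]
        energy += 0.5 * rest_k[c] * dr * dr
        mag = -rest_k[c] * dr / r
        f[i, 0] += mag * dx0
        f[i, 1] += mag * dx1
        f[i, 2] += mag * dx2
        f[j, 0] -= mag * dx0
        f[j, 1] -= mag * dx1
        f[j, 2] -= mag * dx2
    # umbrella on R (pocket-center to ligand-center distance)
    if k_r > 0.0 and poc_idx.shape[0] > 0:
        cp0 = cp1 = cp2 = 0.0
        cl0 = cl1 = cl2 = 0.0
        for a in range(poc_idx.shape[0]):
            i = poc_idx[a]
            cp0 += x[i, 0]
            cp1 += x[i, 1]
            cp2 += x[i, 2]
        for a in range(lig_idx.shape[0]):
            i = lig_idx[a]
            cl0 += x[i, 0]
            cl1 += x[i, 1]
            cl2 += x[i, 2]
        np_ = poc_idx.shape[0]
        nl = lig_idx.shape[0]
        d0 = cp0 / np_ - cl0 / nl
        d1 = cp1 / np_ - cl1 / nl
        d2 = cp2 / np_ - cl2 / nl
        r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        if r > 1e-9:
            dr = r - c_r
            energy += 0.5 * k_r * dr * dr
            gp = -k_r * dr / r / np_
            gl = k_r * dr / r / nl
            for a in range(poc_idx.shape[0]):
                i = poc_idx[a]
                f[i, 0] += gp * d0
                f[i, 1] += gp * d1
                f[i, 2] += gp * d2
            for a in range(lig_idx.shape[0]):
                i = lig_idx[a]
                f[i, 0] += gl * d0
                f[i, 1] += gl * d1
                f[i, 2] += gl * d2
    # harmonic restraint on an alignment-free PC0-like linear CV
    if k_pc0 > 0.0 and pc0_scope.shape[0] > 0:
        val = 0.0
        for a in range(pc0_scope.shape[0]):
            i = pc0_scope[a]
            val += pc0_vec[a, 0] * (x[i, 0] - pc0_mean[a, 0])
            val += pc0_vec[a, 1] * (x[i, 1] - pc0_mean[a, 1])
            val += pc0_vec[a, 2] * (x[i, 2] - pc0_mean[a, 2])
        dv = val - c_pc0
        energy += 0.5 * k_pc0 * dv * dv
        for a in range(pc0_scope.shape[0]):
            i = pc0_scope[a]
            f[i, 0] += -k_pc0 * dv * pc0_vec[a, 0]
            f[i, 1] += -k_pc0 * dv * pc0_vec[a, 1]
            f[i, 2] += -k_pc0 * dv * pc0_vec[a, 2]
    return energy


@njit(cache=True)
def _run(x0, n_steps, stride, dt, gamma, kt, seed,
         bond_idx, bond_r0, k_bond,
         nat_idx, nat_eps, nat_r0, nat_w,
         rb_idx, rb_eps, lam, rc, wsw,
         ev_idx, r_ev, k_ev,
         rest_idx, rest_r0, rest_k,
         poc_idx, lig_idx, k_r, c_r,
         pc0_scope, pc0_vec, pc0_mean, k_pc0, c_pc0):
    np.random.seed(seed)
    n = x0.shape[0]
    x = x0.copy()
    v = np.random.standard_normal((n, 3)) * np.sqrt(kt)
    f = np.zeros((n, 3))
    energy = _forces(x, f, bond_idx, bond_r0, k_bond, nat_idx, nat_eps,
                     nat_r0, nat_w, rb_idx, rb_eps, lam, rc, wsw, ev_idx,
                     r_ev, k_ev, rest_idx, rest_r0, rest_k, poc_idx,
                     lig_idx, k_r, c_r, pc0_scope, pc0_vec, pc0_mean,
                     k_pc0, c_pc0)
    n_rec = n_steps // stride
    frames = np.zeros((n_rec, n, 3))
    energies = np.zeros(n_rec)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kt)
    half = 0.5 * dt
    rec = 0
    bad_step = -1
    for step in range(n_steps):
        # BAOAB
        for i in range(n):
            for d in range(3):
                vv = v[i, d] + half * f[i, d]
                xx = x[i, d] + half * vv
                vv = c1 * vv + c2 * np.random.standard_normal()
                x[i, d] = xx + half * vv
                v[i, d] = vv
        energy = _forces(x, f, bond_idx, bond_r0, k_bond, nat_idx,
                         nat_eps, nat_r0, nat_w, rb_idx, rb_eps, lam, rc,
                         wsw, ev_idx, r_ev, k_ev, rest_idx, rest_r0,
                         rest_k, poc_idx, lig_idx, k_r, c_r, pc0_scope,
                         pc0_vec, pc0_mean, k_pc0, c_pc0)
        for i in range(n):
            for d in range(3):
                v[i, d] += half * f[i, d]
        if not np.isfinite(energy):
            bad_step = step
            break
        if (step + 1) % stride == 0:
            for i in range(n):
                frames[rec, i, 0] = x[i, 0]
                frames[rec, i, 1] = x[i, 1]
                frames[rec, i, 2] = x[i, 2]
            energies[rec] = energy
            rec += 1
    return frames[:rec], energies[:rec], bad_step


@njit(cache=True)
def _run_nve(x0, v0, n_steps, dt,
             bond_idx, bond_r0, k_bond,
             nat_idx, nat_eps, nat_r0, nat_w,
             rb_idx, rb_eps, lam, rc, wsw,
             ev_idx, r_ev, k_ev,
             rest_idx, rest_r0, rest_k,
             poc_idx, lig_idx, k_r, c_r,
             pc0_scope, pc0_vec, pc0_mean, k_pc0, c_pc0):
    """Velocity-Verlet without thermostat; returns total-energy series."""
    x = x0.copy()
    v = v0.copy()
    f = np.zeros_like(x)
    pe = _forces(x, f, bond_idx, bond_r0, k_bond, nat_idx, nat_eps,
                 nat_r0, nat_w, rb_idx, rb_eps, lam, rc, wsw, ev_idx,
                 r_ev, k_ev, rest_idx, rest_r0, rest_k, poc_idx, lig_idx,
                 k_r, c_r, pc0_scope, pc0_vec, pc0_mean, k_pc0, c_pc0)
    etot = np.zeros(n_steps)
    for step in range(n_steps):
        v += 0.5 * dt * f
        x += dt * v
        pe = _forces(x, f, bond_idx, bond_r0, k_bond, nat_idx, nat_eps,
                     nat_r0, nat_w, rb_idx, rb_eps, lam, rc, wsw, ev_idx,
                     r_ev, k_ev, rest_idx, rest_r0, rest_k, poc_idx,
                     lig_idx, k_r, c_r, pc0_scope, pc0_vec, pc0_mean,
                     k_pc0, c_pc0)
        v += 0.5 * dt * f
        ke = 0.5 * np.sum(v * v)
        etot[step] = pe + ke
    return etot


def _kernel_args(topology, biases):
    packed = _pack_biases(biases, topology.n_sites)
    return (
        topology.bond_idx, topology.bond_r0, topology.k_bond,
        topology.nat_idx, topology.nat_eps, topology.nat_r0,
        topology.nat_width,
        topology.rb_idx, topology.rb_eps, topology.lam,
        topology.contact_range, topology.well_width,
        topology.ev_idx, topology.r_ev, topology.k_ev,
    ) + packed


def potential_energy(topology, coords, biases=None):
    """Total potential energy (kcal/mol) of a configuration."""
    f = np.zeros((topology.n_sites, 3))
    return float(_forces(np.asarray(coords, dtype=float), f,
                         *_kernel_args(topology, biases)))


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Strided frames, per-frame potential energy, and run parameters."""

    frames: np.ndarray
    energies: np.ndarray
    seed: int
    dt: float
    gamma: float
    temperature: float
    stride: int

    @property
    def n_frames(self):
        return len(self.frames)


def run_langevin(topology, biases=None, T=300.0, n_steps=10_000,
                 stride=50, seed=0, dt=0.02, gamma=0.25, x0=None):
    """BAOAB Langevin dynamics; bit-reproducible under a fixed seed."""
    if T <= 0:
        raise SimulationError("temperature must be positive")
    if n_steps < 1:
        raise SimulationError("n_steps must be >= 1")
    x0 = np.asarray(
        x0 if x0 is not None else topology.reference.coords, dtype=float)
    frames, energies, bad = _run(
        x0, int(n_steps), int(stride), float(dt), float(gamma),
        KB * T, int(seed) % (2 ** 31),
        *_kernel_args(topology, biases),
    )
    if bad >= 0:
        raise SimulationError(
            f"integration diverged (non-finite energy) at step {bad}"
        )
    if len(energies) and not np.all(np.isfinite(energies)):
        raise SimulationError("non-finite recorded energy")
    return SimulationResult(frames, energies, seed, dt, gamma, T, stride)


def run_nve(topology, biases=None, T=300.0, n_steps=1000, seed=0,
            dt=0.005, x0=None):
    """Unthermostatted velocity-Verlet; returns the total-energy series
    (for energy-conservation checks)."""
    rng = np.random.default_rng(seed)
    x0 = np.asarray(
        x0 if x0 is not None else topology.reference.coords, dtype=float)
    v0 = rng.normal(0.0, np.sqrt(KB * T), x0.shape)
    return _run_nve(x0, v0, int(n_steps), float(dt),
                    *_kernel_args(topology, biases))


# ---------------------------------------------------------------------------
# order-parameter series and umbrella orchestration
# ---------------------------------------------------------------------------

def r_series(frames, topology_structure, pocket_annotation="pocket",
             ligand_chain="B"):
    poc = topology_structure.annotation_indices(pocket_annotation)
    lig = topology_structure.chain_indices(ligand_chain)
    cp = frames[:, poc, :].mean(axis=1)
    cl = frames[:, lig, :].mean(axis=1)
    return np.linalg.norm(cp - cl, axis=1)


def qf_series(frames, topology_structure, reference,
              contact_threshold=12.0, delta_exponent=0.15):
    """Per-frame Q to the open/free reference over inter-domain pairs
    (union contact rule, intra-molecular delta convention)."""
    d1 = topology_structure.annotation_indices("domain1")
    d2 = topology_structure.annotation_indices("domain2")
    ii, jj = np.meshgrid(d1, d2, indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    ref = reference.coords
    dref = np.linalg.norm(ref[ii] - ref[jj], axis=-1)
    res = np.array([s.residue_index for s in topology_structure.sites])
    delta2 = np.abs(res[ii] - res[jj]).astype(float) ** (2 * delta_exponent)
    df = np.linalg.norm(frames[:, ii, :] - frames[:, jj, :], axis=-1)
    within = (df <= contact_threshold) | (dref <= contact_threshold)
    gauss = np.exp(-((df - dref) ** 2) / (2.0 * delta2))
    num = (gauss * within).sum(axis=1)
    cnt = within.sum(axis=1)
    out = np.full(len(frames), np.nan)
    ok = cnt > 0
    out[ok] = num[ok] / cnt[ok]
    return out


def pc0_series(frames, pca_model):
    return np.array([pca_model.project(f) for f in frames])


def run_umbrella_series(topology, base_biases, window_centers, k_bias=2.0,
                        steps_per_window=200_000, T=300.0, seed=0,
                        stride=50, equil_fraction=0.2, pca_model=None,
                        qf_reference=None, pocket_annotation="pocket",
                        ligand_chain="B", min_overlap_bins=1,
                        x0=None, n_sweeps=2):
    """Sequential umbrella windows on R; returns an UmbrellaDataset.

    Windows run in order, each starting from the previous window's final
    configuration (steered initialization keeps neighbor distributions
    overlapping); the first ``equil_fraction`` of each window is
    discarded.  With ``n_sweeps=2`` (default) the series runs outward
    and then back inward, pooling both passes per center, which averages
    pulling hysteresis in slow orthogonal degrees of freedom at no extra
    cost; ``steps_per_window`` is the total per center across sweeps.
    PC0 and Q_f are co-recorded when a PCA model / open reference is
    supplied.  A warning lists neighbor pairs whose R histograms fail to
    overlap.
    """
    import warnings

    centers = list(window_centers)
    if len(centers) == 0:
        raise SimulationError("empty window list")
    if n_sweeps < 1:
        raise SimulationError("n_sweeps must be >= 1")
    ref = topology.reference
    x = np.asarray(x0 if x0 is not None else ref.coords, dtype=float)
    master = np.random.default_rng(seed)
    steps_per_visit = max(1, int(steps_per_window) // int(n_sweeps))

    schedule = []
    for sweep in range(int(n_sweeps)):
        order = range(len(centers)) if sweep % 2 == 0 \
            else range(len(centers) - 1, -1, -1)
        schedule.extend(order)

    per_center = {i: {"r": [], "extra": {}} for i in range(len(centers))}
    for w in schedule:
        c = centers[w]
        wseed = int(master.integers(0, 2 ** 31 - 1))
        biases = list(base_biases or []) + [
            harmonic_r_bias(topology, c, k_bias,
                            pocket_annotation=pocket_annotation,
                            ligand_chain=ligand_chain)
        ]
        result = run_langevin(
            topology, biases, T=T, n_steps=steps_per_visit,
            stride=stride, seed=wseed, x0=x,
        )
        x = result.frames[-1].copy()
        burn = int(equil_fraction * result.n_frames)
        frames = result.frames[burn:]
        bucket = per_center[w]
        rs = r_series(frames, ref, pocket_annotation, ligand_chain)
        bucket["r"].append(rs)
        sweep_id = len(bucket["r"]) - 1
        bucket["extra"].setdefault("sweep", []).append(
            np.full(len(rs), float(sweep_id)))
        if pca_model is not None:
            bucket["extra"].setdefault("pc0", []).append(
                pc0_series(frames, pca_model))
        if qf_reference is not None:
            bucket["extra"].setdefault("q_f", []).append(
                qf_series(frames, ref, qf_reference))

    windows = []
    for i, c in enumerate(centers):
        bucket = per_center[i]
        windows.append(UmbrellaWindow(
            center=float(c), spring_constant=float(k_bias),
            samples=np.concatenate(bucket["r"]),
            extra={k: np.concatenate(v)
                   for k, v in bucket["extra"].items()},
        ))
    dataset = UmbrellaDataset(windows=windows, temperature=T,
                              coordinate="r",
                              metadata={"seed": seed, "k_bias": k_bias})
    if k_bias == 0.0:
        warnings.warn("k_bias = 0: all windows sample the same "
                      "unbiased distribution")
    _warn_overlap_gaps(dataset, min_overlap_bins)
    return dataset


def _warn_overlap_gaps(dataset, min_overlap_bins, n_bins=60):
    import warnings

    lo, hi = dataset.sample_range()
    edges = np.linspace(lo, hi, n_bins + 1)
    gaps = []
    occ = [np.histogram(w.samples, bins=edges)[0] > 0
           for w in dataset.windows]
    order = np.argsort([w.center for w in dataset.windows])
    for a, b in zip(order[:-1], order[1:]):
        if (occ[a] & occ[b]).sum() < min_overlap_bins:
            gaps.append((int(a), int(b)))
    if gaps:
        warnings.warn(f"umbrella neighbor windows without histogram "
                      f"overlap: {gaps}")
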