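"""Contact energetics: atomic-contact counting, the residue--base
specificity potential, binding energies, frustration screening, model
ranking, the peptide sequence scan, and affinity calibration.

The residue--base potential assigns each (residue type, base type) pair a
well depth eps = lambda * (pooled contact count / max pooled count), built
from the atomic contact numbers of a reference bound complex; lambda is
the single global scale later calibrated against a target binding
affinity.  Pair energies use a smooth cosine-tapered well: full depth
within ``contact_range`` (6.5 A), tapering to zero over ``well_width``
(2 A) beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import AA1_TO_3, PROTEIN, RNA


class PotentialError(ValueError):
    pass


# positive part of the Kyte-Doolittle scale, normalized to [0, 1]; used
# by the packaged peptide-scan potential
_HYDRO = {
    "ILE": 1.0, "VAL": 0.933, "LEU": 0.844, "PHE": 0.622, "CYS": 0.556,
    "MET": 0.422, "ALA": 0.4,
}


@dataclass
class ContactPotential:
    """Pairwise interaction table.

    ``protein_pair_strengths`` maps unordered (type, type) tuples to
    signed well depths (negative = attractive); pairs absent from the
    table fall back to ``default_protein_strength``.
    ``residue_base_norm`` holds the normalized (0, 1] residue-base table;
    the effective attraction is ``-lam * residue_base_norm[pair]``.
    """

    protein_pair_strengths: dict = field(default_factory=dict)
    default_protein_strength: float = -1.0
    residue_base_norm: dict = field(default_factory=dict)
    lam: float = 1.0
    well_width: float = 2.0
    contact_range: float = 6.5

    def __post_init__(self):
        if self.lam <= 0:
            raise PotentialError("global scale lambda must be positive")
        table = {}
        for (a, b), v in self.protein_pair_strengths.items():
            if not np.isfinite(v):
                raise PotentialError("well depths must be finite")
            table[(a, b)] = v
            table[(b, a)] = v
        self.protein_pair_strengths = table

    @property
    def residue_base_strengths(self):
        """Effective eps table in (0, lam]."""
        return {k: self.lam * v for k, v in self.residue_base_norm.items()}

    def with_lambda(self, lam):
        return ContactPotential(
            protein_pair_strengths=dict(self.protein_pair_strengths),
            default_protein_strength=self.default_protein_strength,
            residue_base_norm=dict(self.residue_base_norm),
            lam=lam, well_width=self.well_width,
            contact_range=self.contact_range,
        )

    # -- pair energetics ---------------------------------------------------

    def strength(self, type_a, class_a, type_b, class_b):
        """Signed well depth for a site-type pair."""
        if class_a == PROTEIN and class_b == PROTEIN:
            return self.protein_pair_strengths.get(
                (type_a, type_b), self.default_protein_strength)
        if {class_a, class_b} == {PROTEIN, RNA}:
            res, base = (type_a, type_b) if class_a == PROTEIN \
                else (type_b, type_a)
            return -self.lam * self.residue_base_norm.get((res, base), 0.0)
        return 0.0

    def switching(self, r):
        """Cosine-tapered switching function: 1 inside contact_range,
        0 beyond contact_range + well_width."""
        r = np.asarray(r, dtype=float)
        s = np.where(
            r <= self.contact_range, 1.0,
            np.where(
                r >= self.contact_range + self.well_width, 0.0,
                0.5 * (1.0 + np.cos(
                    np.pi * (r - self.contact_range) / self.well_width)),
            ),
        )
        return s if s.ndim else float(s)

    @property
    def max_range(self):
        return self.contact_range + self.well_width

    # -- serialization -----------------------------------------------------

    def to_frame(self):
        rows = [
            {"kind": "protein", "type_a": a, "type_b": b, "strength": v}
            for (a, b), v in sorted(self.protein_pair_strengths.items())
            if a <= b
        ] + [
            {"kind": "residue_base", "type_a": r, "type_b": b,
             "strength": v}
            for (r, b), v in sorted(self.residue_base_norm.items())
        ]
        return pd.DataFrame(rows, columns=["kind", "type_a", "type_b",
                                           "strength"])

    def save_tsv(self, path):
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# lambda={self.lam} well_width={self.well_width} "
                     f"contact_range={self.contact_range} "
                     f"default_protein={self.default_protein_strength}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path):
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            params = dict(kv.split("=") for kv in header)
            df = pd.read_csv(fh, sep="\t")
        prot = {
            (r.type_a, r.type_b): r.strength
            for r in df[df.kind == "protein"].itertuples()
        }
        rb = {
            (r.type_a, r.type_b): r.strength
            for r in df[df.kind == "residue_base"].itertuples()
        }
        return cls(
            protein_pair_strengths=prot, residue_base_norm=rb,
            lam=float(params["lambda"]),
            well_width=float(params["well_width"]),
            contact_range=float(params["contact_range"]),
            default_protein_strength=float(params["default_protein"]),
        )


def hydrophobicity_scan_potential(scale=1.0):
    """Type-differentiating protein potential for peptide scans.

    Well depth -scale * h_a * h_b from the positive Kyte-Doolittle part:
    hydrophobic pairs attract, polar residues contribute nothing.  Pairs
    absent from the table default to zero.
    """
    table = {
        (a, b): -scale * ha * hb
        for a, ha in _HYDRO.items() for b, hb in _HYDRO.items()
    }
    return ContactPotential(
        protein_pair_strengths=table, default_protein_strength=0.0,
    )


# ---------------------------------------------------------------------------
# atomic contact counting and potential construction
# ---------------------------------------------------------------------------

def count_atomic_contacts(reference, cutoff=None):
    """Contact counts (residue_index, base_index) -> n atom pairs within
    cutoff.

    If the structure carries pseudo heavy atoms (``heavy_atoms``
    attribute), those plus the site itself are the residue's atom set and
    the cutoff defaults to 4.5 A; at pure CG resolution each site is its
    only atom and the cutoff defaults to 8 A.
    """
    heavy = getattr(reference, "heavy_atoms", None)
    has_atomic = heavy is not None
    heavy = heavy or {}
    if cutoff is None:
        cutoff = 4.5 if has_atomic else 8.0
    classes = reference.molecule_class_array()
    if RNA not in classes:
        raise PotentialError("reference contains no RNA chain")
    if PROTEIN not in classes:
        raise PotentialError("reference contains no protein chain")
    if cutoff <= 0:
        return {}
    coords = reference.coords

    def atoms(i):
        own = coords[i][None, :]
        extra = heavy.get(i)
        return own if extra is None else np.vstack([own, extra])

    counts = {}
    prot_idx = np.nonzero(classes == PROTEIN)[0]
    rna_idx = np.nonzero(classes == RNA)[0]
    for i in prot_idx:
        ai = atoms(i)
        for j in rna_idx:
            aj = atoms(j)
            d = np.linalg.norm(ai[:, None] - aj[None, :], axis=-1)
            c = int((d <= cutoff).sum())
            if c:
                counts[(reference.sites[i].residue_index,
                        reference.sites[j].residue_index)] = c
    return counts


def build_residue_base_potential(reference, contact_counts, lam=1.0,
                                 **kwargs):
    """Residue--base potential from reference contact counts.

    Counts are pooled over instances by (residue type, base type) and
    divided by the maximum pooled count, so the normalized table lies in
    (0, 1] and eps = lam * normalized in (0, lam].  Type pooling (rather
    than per-instance wells) is what lets the same table score new
    sequences in the scan stage.
    """
    if not contact_counts:
        raise PotentialError("empty contact counts")
    res_lookup = {
        (s.chain_id, s.residue_index): s
        for s in reference.sites
    }
    by_res = {s.residue_index: s for s in reference.sites
              if s.molecule_class == PROTEIN}
    by_base = {s.residue_index: s for s in reference.sites
               if s.molecule_class == RNA}
    pooled = {}
    for (res_idx, base_idx), c in contact_counts.items():
        if c < 0:
            raise PotentialError("negative contact count")
        key = (by_res[res_idx].residue_type, by_base[base_idx].residue_type)
        pooled[key] = pooled.get(key, 0) + c
    top = max(pooled.values())
    if top == 0:
        raise PotentialError("all-zero contact counts")
    norm = {k: v / top for k, v in pooled.items() if v > 0}
    return ContactPotential(residue_base_norm=norm, lam=lam, **kwargs)


# ---------------------------------------------------------------------------
# binding energy
# ---------------------------------------------------------------------------

def _partner_indices(structure, partner):
    if isinstance(partner, str):
        partner = {partner}
    idx = []
    for p in partner:
        if p in structure.chain_table:
            idx.extend(structure.chain_indices(p))
        else:
            idx.extend(structure.annotation_indices(p))
    return np.unique(np.asarray(idx, dtype=int))


def binding_energy(complex_structure, partner_a, partner_b, potential):
    """Interaction energy between two disjoint site groups (kcal/mol).

    Sum over inter-partner pairs of signed well depth times the switching
    function; more negative = stronger binding.  Invariant under rigid
    motion of the whole complex.
    """
    ia = _partner_indices(complex_structure, partner_a)
    ib = _partner_indices(complex_structure, partner_b)
    if len(ia) == 0 or len(ib) == 0:
        raise PotentialError("empty partner set")
    if set(ia) & set(ib):
        raise PotentialError("partner sets overlap")
    coords = complex_structure.coords
    d = np.linalg.norm(coords[ia][:, None] - coords[ib][None, :], axis=-1)
    s = potential.switching(d)
    total = 0.0
    sites = complex_structure.sites
    for p, i in enumerate(ia):
        for q, j in enumerate(ib):
            if s[p, q] == 0.0:
                continue
            total += potential.strength(
                sites[i].residue_type, sites[i].molecule_class,
                sites[j].residue_type, sites[j].molecule_class,
            ) * s[p, q]
    return float(total)


# ---------------------------------------------------------------------------
# frustration
# ---------------------------------------------------------------------------

@dataclass
class FrustrationReport:
    """Per-contact frustration z-scores and the minimally frustrated
    count (z above threshold, the frustratometer convention)."""

    contacts: pd.DataFrame
    z_threshold: float

    @property
    def n_minimally_frustrated(self):
        return int((self.contacts["z"] > self.z_threshold).sum())


def _frustration_contacts(structure, potential):
    """Inter-domain / inter-molecular site pairs within interaction
    range."""
    coords = structure.coords
    sites = structure.sites
    dom = np.full(structure.n_sites, -1)
    for k, name in enumerate(("domain1", "domain2")):
        if name in structure.domain_annotations:
            dom[structure.annotation_indices(name)] = k
    pairs = []
    n = structure.n_sites
    for i in range(n):
        for j in range(i + 1, n):
            inter_mol = sites[i].chain_id != sites[j].chain_id
            inter_dom = (dom[i] >= 0 and dom[j] >= 0 and dom[i] != dom[j])
            if not (inter_mol or inter_dom):
                continue
            r = np.linalg.norm(coords[i] - coords[j])
            if r < potential.max_range:
                pairs.append((i, j, r))
    return pairs


def frustration_zscores(structure, potential, n_decoys=1000, seed=0,
                        z_threshold=0.78):
    """Mutational-frustration z-scores for the structure's contacts.

    For every inter-domain/inter-molecular contact the native energy is
    compared against decoys in which the two identities are redrawn from
    the structure's own composition (per molecule class):
    z = (mean decoy - native) / SD(decoy).  Contacts with z above the
    threshold (0.78 by default) are minimally frustrated.
    """
    if n_decoys < 100:
        raise PotentialError("need at least 100 decoys")
    rng = np.random.default_rng(seed)
    pairs = _frustration_contacts(structure, potential)
    if not pairs:
        raise PotentialError("no contacts to evaluate")
    comp = {}
    for s in structure.sites:
        comp.setdefault(s.molecule_class, []).append(s.residue_type)
    rows = []
    for i, j, r in pairs:
        si, sj = structure.sites[i], structure.sites[j]
        sw = potential.switching(r)
        native = potential.strength(
            si.residue_type, si.molecule_class,
            sj.residue_type, sj.molecule_class) * sw
        ti = rng.choice(comp[si.molecule_class], size=n_decoys)
        tj = rng.choice(comp[sj.molecule_class], size=n_decoys)
        dec = np.array([
            potential.strength(a, si.molecule_class, b, sj.molecule_class)
            for a, b in zip(ti, tj)
        ]) * sw
        sd = dec.std()
        if sd <= 1e-12 * max(1.0, abs(dec.mean())):
            raise PotentialError(
                f"contact ({si.chain_id}/{si.residue_index}, "
                f"{sj.chain_id}/{sj.residue_index}) has zero decoy "
                "variance"
            )
        rows.append({
            "site_a": i, "site_b": j, "r": r, "native_energy": native,
            "decoy_mean": dec.mean(), "decoy_sd": sd,
            "z": (dec.mean() - native) / sd,
        })
    return FrustrationReport(pd.DataFrame(rows), z_threshold)


def rank_models(ensemble, potential, n_decoys=1000, seed=0,
                z_threshold=0.78):
    """Energy + minimally-frustrated-contact table over ensemble frames.

    The selected frame maximizes the minimally frustrated count, with
    ties broken by lowest energy.  Returns (DataFrame, selected index).
    """
    rows = []
    for f in range(ensemble.n_frames):
        s = ensemble.structure(f)
        rep = frustration_zscores(s, potential, n_decoys=n_decoys,
                                  seed=seed + f, z_threshold=z_threshold)
        energy = float(rep.contacts["native_energy"].sum())
        rows.append({"frame": f, "energy": energy,
                     "n_minimally_frustrated": rep.n_minimally_frustrated})
    df = pd.DataFrame(rows)
    order = df.sort_values(
        ["n_minimally_frustrated", "energy", "frame"],
        ascending=[False, True, True], kind="stable",
    )
    return df, int(order.iloc[0]["frame"])


# ---------------------------------------------------------------------------
# sequence scan
# ---------------------------------------------------------------------------

def scan_sequence_binding(sequence, partner_complex, peptide_annotation,
                          potential, partner=None):
    """Thread sequence windows onto the peptide sites and score binding.

    For each 1-based window start the window's residue types replace the
    peptide's, and the peptide--partner binding energy is evaluated with
    the given potential.  Returns (DataFrame[start_index, energy],
    reference_energy of the original peptide sequence).
    """
    pep_idx = partner_complex.annotation_indices(peptide_annotation)
    if partner is None:
        pep_chains = {partner_complex.sites[i].chain_id for i in pep_idx}
        part_idx = np.array([
            i for i in range(partner_complex.n_sites)
            if partner_complex.sites[i].chain_id not in pep_chains
        ])
    else:
        part_idx = _partner_indices(partner_complex, partner)
    length = len(pep_idx)
    if len(sequence) < length:
        raise PotentialError("sequence shorter than the peptide")
    coords = partner_complex.coords
    d = np.linalg.norm(
        coords[pep_idx][:, None] - coords[part_idx][None, :], axis=-1)
    sw = potential.switching(d)
    part_types = [partner_complex.sites[j].residue_type for j in part_idx]
    part_classes = [partner_complex.sites[j].molecule_class
                    for j in part_idx]

    def window_energy(types3):
        total = 0.0
        for p in range(length):
            for q in range(len(part_idx)):
                if sw[p, q] == 0.0:
                    continue
                total += potential.strength(
                    types3[p], PROTEIN, part_types[q], part_classes[q]
                ) * sw[p, q]
        return total

    ref_types = [partner_complex.sites[i].residue_type for i in pep_idx]
    reference_energy = window_energy(ref_types)

    rows = []
    for start in range(1, len(sequence) - length + 2):
        window = sequence[start - 1:start - 1 + length]
        try:
            types3 = [AA1_TO_3[ch] for ch in window]
        except KeyError as exc:
            raise PotentialError(
                f"residue {exc.args[0]!r} at window {start} not in the "
                "potential alphabet"
            ) from None
        rows.append({"start_index": start, "energy": window_energy(types3)})
    return pd.DataFrame(rows), float(reference_energy)


# ---------------------------------------------------------------------------
# affinity calibration
# ---------------------------------------------------------------------------

def calibrate_scale(affinity_fn, target_affinity, tolerance=0.5,
                    bracket=(1.0, 2.0), max_expand=4, max_iter=12):
    """Bisection on the global scale lambda to hit a target affinity.

    ``affinity_fn(lam) -> (dG, err)`` re-estimates the binding free
    energy (umbrella + WHAM in the pipeline).  The bracket is expanded
    geometrically until it straddles the target; monotonicity of affinity
    in lambda is checked on the bracket ends.  Returns
    (lambda, achieved_dG, err).
    """
    if target_affinity <= 0:
        raise PotentialError("target affinity must be positive")
    lo, hi = bracket
    cache = {}

    def f(lam):
        if lam not in cache:
            cache[lam] = affinity_fn(lam)
        return cache[lam]

    for _ in range(max_expand):
        if f(lo)[0] <= target_affinity:
            break
        lo /= 2.0
    for _ in range(max_expand):
        if f(hi)[0] >= target_affinity:
            break
        hi *= 2.0
    g_lo, g_hi = f(lo)[0], f(hi)[0]
    if not (g_lo <= target_affinity <= g_hi):
        raise PotentialError(
            f"could not bracket target {target_affinity}: affinity in "
            f"[{g_lo:.2f}, {g_hi:.2f}] over lambda [{lo:.3g}, {hi:.3g}]"
        )
    if g_hi < g_lo:
        raise PotentialError("affinity not monotone over the bracket")
    best = None
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        g, err = f(mid)
        best = (mid, g, err)
        if abs(g - target_affinity) <= tolerance:
            return best
        if g < target_affinity:
            lo = mid
        else:
            hi = mid
    return best
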