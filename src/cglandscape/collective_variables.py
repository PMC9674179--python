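"""Order parameters: cartesian PCA (PC0), the RNA--pocket distance R,
basin assignment and dissociation-pathway classification.

PCA is performed on iteratively superposed coordinates (rigid-body
least-squares alignment to the evolving mean) so that the leading
components capture internal motion — here the open/closed hinge — rather
than overall rotation.  The sign of PC0 is anchored so that the open
reference conformer projects positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CVError(ValueError):
    pass


def _kabsch(mobile, target):
    """Rotation + translation superposing ``mobile`` onto ``target``
    (both (m, 3)); returns transformed mobile coordinates."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return mc @ rot.T + target.mean(axis=0)


def _resolve_scope(topology, atom_scope):
    if atom_scope is None:
        return np.arange(topology.n_sites)
    if isinstance(atom_scope, str):
        return topology.annotation_indices(atom_scope)
    if isinstance(atom_scope, (list, tuple)) and atom_scope and \
            isinstance(atom_scope[0], str):
        idx = np.concatenate([
            topology.annotation_indices(a) for a in atom_scope
        ])
        return np.unique(idx)
    return np.asarray(atom_scope, dtype=int)


@dataclass
class PCAModel:
    """Fitted cartesian PCA over a site scope.

    ``components`` are orthonormal rows over flattened (3m) coordinates
    with non-increasing ``explained_variance`` (A^2); ``mean_coords`` is
    the converged aligned mean and also the alignment reference for
    projection.  ``sign_convention`` records which reference was used to
    orient PC0 positive.
    """

    scope_idx: np.ndarray
    mean_coords: np.ndarray           # (m, 3)
    components: np.ndarray            # (n_comp, 3m)
    explained_variance: np.ndarray    # (n_comp,)
    sign_convention: str = "unanchored"

    def project(self, coords_or_structure, component=0):
        """Project a structure (or raw scope coordinates) onto a component
        after superposition onto the model mean."""
        x = self._scope_coords(coords_or_structure)
        aligned = _kabsch(x, self.mean_coords)
        dev = (aligned - self.mean_coords).ravel()
        return float(dev @ self.components[component])

    def _scope_coords(self, obj):
        coords = obj.coords if hasattr(obj, "coords") else np.asarray(obj)
        if coords.shape[0] == len(self.scope_idx):
            return coords
        if coords.shape[0] > self.scope_idx.max():
            return coords[self.scope_idx]
        raise CVError("structure incongruent with PCA scope")


def fit_pca(ensemble, atom_scope=None, n_components=5, open_reference=None,
            max_iter=20, tol=1e-8):
    """Fit cartesian PCA to an ensemble after iterative superposition.

    Parameters
    ----------
    ensemble : Ensemble
    atom_scope : annotation name(s) or site indices, optional
        Sites entering the PCA (all sites by default).
    open_reference : CGStructure, optional
        Conformer anchoring the PC0 sign convention (projects positive).

    Returns
    -------
    PCAModel
    """
    if ensemble.n_frames < 2:
        raise CVError("need at least 2 frames")
    idx = _resolve_scope(ensemble.topology, atom_scope)
    if len(idx) == 0:
        raise CVError("empty atom scope")
    x = ensemble.frames[:, idx, :].copy()
    mean = x[0] - x[0].mean(axis=0)
    for _ in range(max_iter):
        aligned = np.array([_kabsch(f, mean) for f in x])
        new_mean = aligned.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    aligned = np.array([_kabsch(f, mean) for f in x])
    flat = aligned.reshape(len(x), -1) - mean.ravel()
    n_components = min(n_components, flat.shape[0] - 1, flat.shape[1])
    # SVD of the centered data matrix; rank-deficient ensembles (all
    # frames identical) yield zero variance rather than an error
    u, s, vt = np.linalg.svd(flat, full_matrices=False)
    var = s ** 2 / len(x)
    if np.all(var < 1e-20):
        import warnings
        warnings.warn("ensemble has zero variance; PCA model is degenerate")
    comps = vt[:n_components]
    model = PCAModel(
        scope_idx=idx, mean_coords=mean, components=comps,
        explained_variance=var[:n_components],
    )
    if open_reference is not None:
        p = model.project(open_reference)
        if p < 0:
            model.components = model.components.copy()
            model.components[0] = -model.components[0]
        model.sign_convention = "open_reference_positive"
    return model


def project_pc0(model, structure):
    """PC0 value of a structure under a fitted PCA model."""
    return model.project(structure, component=0)


def compute_r(structure, pocket_annotation="pocket", ligand_chain="B"):
    """Distance between the geometric centers of the pocket residues and
    the ligand sites (Angstrom)."""
    try:
        pocket = structure.annotation_indices(pocket_annotation)
    except ValueError as exc:
        raise CVError(str(exc)) from None
    if len(pocket) == 0:
        raise CVError("empty pocket annotation")
    if ligand_chain in structure.chain_table:
        lig = structure.chain_indices(ligand_chain)
    else:
        lig = structure.annotation_indices(ligand_chain)
    coords = structure.coords
    return float(np.linalg.norm(
        coords[pocket].mean(axis=0) - coords[lig].mean(axis=0)
    ))


@dataclass
class OrderParameterFrame:
    """Per-frame order parameters: PC0, Q to the free/open reference over
    inter-domain pairs (q_f), and the RNA--pocket distance R (Angstrom)."""

    pc0: float
    q_f: float = np.nan
    r_dist: float = np.nan

    def __post_init__(self):
        if np.isfinite(self.q_f) and not (0.0 <= self.q_f <= 1.0):
            raise CVError("q_f must lie in [0, 1]")
        if np.isfinite(self.r_dist) and self.r_dist < 0:
            raise CVError("r_dist must be >= 0")

    def value(self, name):
        return {"pc0": self.pc0, "q_f": self.q_f, "r": self.r_dist}[name]


def _rects_overlap(a, b):
    shared = set(a) & set(b)
    if not shared:
        return True  # unconstrained in any shared direction -> overlap
    return all(a[k][0] < b[k][1] and b[k][0] < a[k][1] for k in shared)


def assign_basin(frame, basin_defs):
    """Label a frame by disjoint rectangles in order-parameter space.

    ``basin_defs`` maps label -> {param: (lo, hi)} with params among
    'pc0', 'q_f', 'r'.  Rectangles must be pairwise disjoint; a frame in
    no rectangle gets 'unassigned'.
    """
    names = list(basin_defs)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if _rects_overlap(basin_defs[a], basin_defs[b]):
                raise CVError(f"basin definitions {a!r} and {b!r} overlap")
    for label, rect in basin_defs.items():
        if all(lo <= frame.value(k) <= hi for k, (lo, hi) in rect.items()):
            return label
    return "unassigned"


def default_basins(pc0_closed, pc0_open, width=None):
    """Open/closed basin rectangles around two fitted PC0 anchors.

    Emulates the printed mode ranges (closed mode spanning [-10, 0], open
    mode [10, 30] in the source system) rescaled to the synthetic PC0
    axis: each basin is a symmetric interval around its anchor with half
    the anchor separation as default width.
    """
    if width is None:
        width = abs(pc0_open - pc0_closed) / 2.0 * 0.9
    return {
        "II": {"pc0": (pc0_closed - width, pc0_closed + width)},
        "I": {"pc0": (pc0_open - width, pc0_open + width)},
    }


def classify_pathway(trajectory, thresholds):
    """Classify a dissociation trajectory as path_I / path_II / mixed.

    ``thresholds`` needs: r_bound (start must be below), r_unbound
    (crossing completes dissociation), pc0_open (entering the open range)
    and pc0_closed (staying at or below = closed).  path_I: the receptor
    opens before the ligand finishes unbinding; path_II: unbinding
    completes while PC0 never leaves the closed range; mixed otherwise.
    """
    frames = list(trajectory)
    if not frames:
        raise CVError("empty trajectory")
    if frames[0].r_dist >= thresholds["r_bound"]:
        raise CVError("trajectory does not start bound")
    unbind_step = next(
        (i for i, f in enumerate(frames)
         if f.r_dist >= thresholds["r_unbound"]), None)
    if unbind_step is None:
        raise CVError("no dissociation event in trajectory")
    open_step = next(
        (i for i, f in enumerate(frames)
         if f.pc0 >= thresholds["pc0_open"]), None)
    if open_step is not None and open_step <= unbind_step:
        return "path_I"
    stayed_closed = all(
        f.pc0 <= thresholds["pc0_closed"] for f in frames[:unbind_step + 1]
    )
    if stayed_closed:
        return "path_II"
    return "mixed"
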