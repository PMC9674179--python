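"""Mutual-Q structural similarity, template screening and Q-clustering.

The mutual Q between structures A and B averages Gaussian-weighted
agreement of inter-site distances over a pair set::

    Q = (1/N) sum_ij exp( -(r_ij^A - r_ij^B)^2 / (2 delta_ij^2) )

with ``delta_ij = |i - j|**0.15`` (Angstrom) for intra-molecular pairs and
``delta_ij^2 = 5`` Angstrom^2 for inter-molecular pairs.  A pair enters the
set when the two sites are within the contact threshold (12 Angstrom by
default) in either structure (union rule), subject to the scope rule
(all / inter-domain / inter-molecular / template contacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structures import CGStructure, Ensemble


class SimilarityError(ValueError):
    pass


@dataclass
class QSpec:
    """Configuration of the Q pair set and Gaussian widths.

    pair_scope: 'all', 'inter_domain', 'inter_molecular' or
    'template_contacts'.  ``domains``: list of annotation names partitioning
    the receptor into domains, required for 'inter_domain' scope.
    ``min_sequence_separation`` excludes trivially constrained short-range
    intra-molecular pairs (|i-j| < 3 by default).
    """

    pair_scope: str = "all"
    contact_threshold: float = 12.0
    delta_intra_exponent: float = 0.15
    delta_inter_sq: float = 5.0
    min_sequence_separation: int = 3
    domains: list = field(default_factory=list)

    def __post_init__(self):
        if self.contact_threshold <= 0:
            raise SimilarityError("contact threshold must be positive")
        if self.delta_intra_exponent < 0:
            raise SimilarityError("delta exponent must be >= 0")


def _chain_ids(structure):
    return np.array([s.chain_id for s in structure.sites])


def _domain_labels(structure, spec):
    """Per-site domain label (-1 = unassigned) from spec.domains."""
    labels = np.full(structure.n_sites, -1, dtype=int)
    for k, name in enumerate(spec.domains):
        labels[structure.annotation_indices(name)] = k
    return labels


def _pair_set(a, b, spec):
    """Index pairs (i, j), i<j, passing scope + union contact threshold."""
    n = a.n_sites
    ca, cb = a.coords, b.coords
    da = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    db = np.linalg.norm(cb[:, None, :] - cb[None, :, :], axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    within = (da[iu, ju] <= spec.contact_threshold) | \
             (db[iu, ju] <= spec.contact_threshold)

    chains = _chain_ids(a)
    same_chain = chains[iu] == chains[ju]
    res_idx = np.array([s.residue_index for s in a.sites])
    seqsep = np.abs(res_idx[iu] - res_idx[ju])
    # short-range intra-molecular pairs are constrained by connectivity
    trivial = same_chain & (seqsep < spec.min_sequence_separation)

    if spec.pair_scope == "all":
        scope = ~trivial
    elif spec.pair_scope == "inter_molecular":
        scope = ~same_chain
    elif spec.pair_scope == "inter_domain":
        if not spec.domains:
            raise SimilarityError(
                "inter_domain scope requires spec.domains annotations"
            )
        dom = _domain_labels(a, spec)
        di, dj = dom[iu], dom[ju]
        scope = (di >= 0) & (dj >= 0) & (di != dj) & ~trivial
    else:
        raise SimilarityError(f"unknown pair scope {spec.pair_scope!r}")

    keep = within & scope
    return iu[keep], ju[keep], da[iu[keep], ju[keep]], db[iu[keep], ju[keep]]


def _delta_sq(a, iu, ju, spec):
    """Squared Gaussian widths per pair (intra: |i-j|^0.3, inter: 5 A^2)."""
    chains = _chain_ids(a)
    res_idx = np.array([s.residue_index for s in a.sites])
    same_chain = chains[iu] == chains[ju]
    seqsep = np.abs(res_idx[iu] - res_idx[ju]).astype(float)
    d2 = np.full(len(iu), spec.delta_inter_sq, dtype=float)
    intra = same_chain
    d2[intra] = np.power(seqsep[intra], 2.0 * spec.delta_intra_exponent)
    return d2


def _q_from_pairs(da, db, d2):
    return float(np.mean(np.exp(-((da - db) ** 2) / (2.0 * d2))))


def mutual_q(a, b, spec=None):
    """Mutual Q between two structures sharing a topology.

    Returns a value in [0, 1]; 1 for identical coordinates.  Symmetric in
    its arguments and invariant under rigid-body motion (depends only on
    internal distances).
    """
    spec = spec or QSpec()
    if not a.same_topology(b):
        raise SimilarityError("structures do not share a topology")
    iu, ju, da, db = _pair_set(a, b, spec)
    if len(iu) == 0:
        raise SimilarityError("empty pair set under the given QSpec")
    d2 = _delta_sq(a, iu, ju, spec)
    return _q_from_pairs(da, db, d2)


def q_to_template(model, template, mapping=None, spec=None):
    """Q of a model against a reference template over union-of-contacts
    inter-molecular pairs (Q_c).

    ``mapping`` maps model site index -> template site index (injective);
    identity when omitted.  Only inter-molecular pairs forming a contact in
    the template or in the model enter the pair set.
    """
    spec = spec or QSpec(pair_scope="inter_molecular")
    n = model.n_sites
    if mapping is None:
        if n != template.n_sites:
            raise SimilarityError("sizes differ; a mapping is required")
        mapping = {i: i for i in range(n)}
    if len(set(mapping.values())) != len(mapping):
        raise SimilarityError("mapping must be injective")

    midx = np.array(sorted(mapping.keys()))
    tidx = np.array([mapping[i] for i in midx])
    cm = model.coords[midx]
    ct = template.coords[tidx]
    chains_m = _chain_ids(model)[midx]

    k = len(midx)
    iu, ju = np.triu_indices(k, k=1)
    inter = chains_m[iu] != chains_m[ju]
    dm = np.linalg.norm(cm[:, None] - cm[None, :], axis=-1)[iu, ju]
    dt = np.linalg.norm(ct[:, None] - ct[None, :], axis=-1)[iu, ju]
    within = (dm <= spec.contact_threshold) | (dt <= spec.contact_threshold)
    keep = inter & within
    if not np.any(keep):
        raise SimilarityError("no inter-molecular contact pairs in union set")
    d2 = np.full(int(keep.sum()), spec.delta_inter_sq)
    return _q_from_pairs(dm[keep], dt[keep], d2)


def screen_by_qc(models, template, threshold=0.2, mapping=None, spec=None):
    """Select models with Q_c strictly greater than ``threshold``.

    Returns (selected indices, all Q_c values).  The inequality is strict:
    a model at exactly the threshold is not selected.
    """
    qcs = np.array([
        q_to_template(m, template, mapping=mapping, spec=spec) for m in models
    ])
    return np.nonzero(qcs > threshold)[0], qcs


def pairwise_q_matrix(ensemble, spec=None):
    """Symmetric matrix of mutual Q between all frame pairs of an ensemble."""
    spec = spec or QSpec()
    n = ensemble.n_frames
    if n < 2:
        raise SimilarityError("need at least 2 frames")
    # pair set bookkeeping is identical across frames; compute per pair
    mat = np.eye(n)
    structs = [ensemble.structure(i) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = mutual_q(structs[i], structs[j], spec)
    return mat


def cluster_by_q(q_matrix, k):
    """Average-linkage hierarchical clustering on distance 1 - Q.

    Returns (labels, representatives): labels are 0-based cluster ids in
    order of first appearance; the representative of a cluster is the frame
    maximizing mean within-cluster Q (ties to lowest frame index).
    """
    q_matrix = np.asarray(q_matrix, dtype=float)
    n = q_matrix.shape[0]
    if not (1 <= k <= n):
        raise SimilarityError(f"k={k} out of range for {n} frames")
    dist = 1.0 - q_matrix
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    if k == n:
        labels = np.arange(n)
    else:
        z = linkage(squareform(dist, checks=False), method="average")
        raw = fcluster(z, t=k, criterion="maxclust")
        # relabel in order of first appearance for determinism
        remap, labels = {}, np.empty(n, dtype=int)
        for i, lab in enumerate(raw):
            labels[i] = remap.setdefault(lab, len(remap))
    reps = {}
    for lab in sorted(set(labels.tolist())):
        members = np.nonzero(labels == lab)[0]
        if len(members) == 1:
            reps[lab] = int(members[0])
            continue
        sub = q_matrix[np.ix_(members, members)]
        mean_q = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
        reps[lab] = int(members[np.argmax(mean_q)])  # argmax: lowest on ties
    return labels, reps


def contact_frequency_map(ensemble, group_a, group_b, threshold=12.0,
                          min_count=None):
    """Contact frequency between two site groups across ensemble frames.

    Returns a dict ``(residue_index_a, residue_index_b) -> count`` of frames
    in which the pair is within ``threshold``; with ``min_count`` set, pairs
    below it are dropped (e.g. >30 of 60 predictions).
    """
    topo = ensemble.topology
    ia = topo.annotation_indices(group_a) if isinstance(group_a, str) \
        else np.asarray(group_a)
    ib = topo.annotation_indices(group_b) if isinstance(group_b, str) \
        else np.asarray(group_b)
    counts = np.zeros((len(ia), len(ib)), dtype=int)
    for f in range(ensemble.n_frames):
        c = ensemble.frames[f]
        d = np.linalg.norm(c[ia][:, None] - c[ib][None, :], axis=-1)
        counts += d <= threshold
    out = {}
    for p, i in enumerate(ia):
        for q, j in enumerate(ib):
            c = int(counts[p, q])
            if c and (min_count is None or c > min_count):
                out[(topo.sites[i].residue_index,
                     topo.sites[j].residue_index)] = c
    return out
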