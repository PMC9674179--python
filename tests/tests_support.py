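"""Shared oracle helpers for the test suite."""

import numpy as np

from cglandscape import potentials as pot
from cglandscape import similarity as sim
from cglandscape.structures import CGSite, CGStructure, PROTEIN


def hand_pair_values():
    """Mutual Q of single-pair systems evaluated by the library,
    compared by the caller against hand computation of the Gaussian
    similarity formula.

    inter-molecular pair: r_A = 6, r_B = 7 -> exp(-1/10)
    intra pair |i-j| = 2: |r_A - r_B| = 1 -> exp(-1/(2*2^0.3))
    """
    def two_chain(r):
        return CGStructure([
            CGSite("A", 1, "ALA", PROTEIN, [0.0, 0.0, 0.0]),
            CGSite("B", 1, "GLY", PROTEIN, [r, 0.0, 0.0]),
        ])

    inter = sim.mutual_q(two_chain(6.0), two_chain(7.0),
                         sim.QSpec(pair_scope="inter_molecular"))

    def one_chain(r):
        return CGStructure([
            CGSite("A", 1, "ALA", PROTEIN, [0.0, 0.0, 0.0]),
            CGSite("A", 2, "GLY", PROTEIN, [0.0, 100.0, 0.0]),
            CGSite("A", 3, "LYS", PROTEIN, [r, 0.0, 0.0]),
        ])

    intra = sim.mutual_q(one_chain(10.0), one_chain(11.0),
                         sim.QSpec(min_sequence_separation=2))
    return inter, intra


def two_type_planted_complex():
    """Two strands, one strong ILE-ILE contact in a SER background."""
    sites = []
    for i, t in enumerate(["ILE", "SER", "SER", "SER", "SER", "SER"]):
        sites.append(CGSite("A", i + 1, t, PROTEIN, [0.0, 3.8 * i, 0.0]))
    for i, t in enumerate(["ILE", "SER", "SER", "SER", "SER", "SER"]):
        sites.append(CGSite("B", i + 1, t, PROTEIN, [5.0, 3.8 * i, 0.0]))
    return CGStructure(sites)


def two_type_frustration_check(n_decoys=10000, seed=3):
    """Monte-Carlo vs exact decoy statistics for the 2-type composition.

    Returns (mc_z, exact_z, se_z) for the planted strong contact, where
    the exact values come from the closed-form two-point decoy energy
    distribution (ILE fraction f -> P(ILE,ILE) = f^2).
    """
    s = two_type_planted_complex()
    p = pot.hydrophobicity_scan_potential(1.0)
    rep = pot.frustration_zscores(s, p, n_decoys=n_decoys, seed=seed)
    row = rep.contacts.iloc[rep.contacts.native_energy.idxmin()]
    f_i = 2.0 / 12.0
    e_strong = -1.0  # ILE-ILE well depth before the switching factor
    p_strong = f_i * f_i
    mean = e_strong * p_strong
    var = p_strong * (e_strong - mean) ** 2 + (1 - p_strong) * mean ** 2
    sw = row.native_energy / e_strong  # distance switching factor
    exact_z = (mean * sw - row.native_energy) / (np.sqrt(var) * sw)
    # SE of the z estimate is dominated by the decoy-mean uncertainty
    se = 1.0 / np.sqrt(n_decoys)
    return row.z, exact_z, se
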