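"""Reported equilibrium constants for the CID/NCBD variant panel.

These are published experimental values used as consistency-check and
simulation inputs: the ten ITC dissociation constants measured between
the deuterostome/protostome (D/P) ancestral NCBD variants and the 1R
ancestral CID variants, the urea-denaturation parameters of selected
NCBD variants, and the reference affinity used to normalise relative
affinities (extant human NCOA2 CID with p300 NCBD).
"""

#: Kd (uM) for D/P NCBD (Thr2062 "wild type" and six point variants) with
#: 1R CID, plus D/P NCBD with three 1R CID point variants.
DP_NCBD_1R_CID_KD_UM = {
    ("D/P NCBD", "1R CID"): 3.0,
    ("D/P NCBD T2062I", "1R CID"): 2.0,
    ("D/P NCBD T2062V", "1R CID"): 2.2,
    ("D/P NCBD P2063L", "1R CID"): 7.7,
    ("D/P NCBD Q2088H", "1R CID"): 1.5,
    ("D/P NCBD Q2088N", "1R CID"): 2.2,
    ("D/P NCBD H2107Q", "1R CID"): 18.0,
    ("D/P NCBD", "1R CID S1058N"): 3.9,
    ("D/P NCBD", "1R CID G1080S"): 4.8,
    ("D/P NCBD", "1R CID S1078Q"): 5.5,
}

#: Kd (uM) of the reference interaction for relative affinities.
REFERENCE_KD_UM = 0.071  # human NCOA2 CID with p300 NCBD

#: Urea denaturation of NCBD variants (10 C, 1 M TMAO).
#: midpoint_shared uses the globally shared m-value; midpoint_free / m_free
#: come from per-curve free fits.
UREA_SHARED_M_KCAL_MOL_M = 0.61
UREA_DENATURATION = {
    "D/P": {"midpoint_shared": 2.4, "midpoint_free": 2.2, "m_free": 0.56},
    "D/P T2062I": {"midpoint_shared": 3.3, "midpoint_free": 3.4, "m_free": 0.70},
    "1R/2R": {"midpoint_shared": 4.4, "midpoint_free": 4.4, "m_free": 0.67},
    "Fish/tetrapod CREBBP": {
        "midpoint_shared": 4.0,
        "midpoint_free": 4.0,
        "m_free": 0.62,
    },
}

#: TFE-induced helix formation of CID variants (25 C); shared m in %^-1.
TFE_SHARED_M_PER_PERCENT = 0.17
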