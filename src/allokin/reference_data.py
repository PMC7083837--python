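"""Published reference potencies for SERT allosteric pharmacology.

These are reported experimental values (nM) used as inputs for worked
examples and regression checks: equilibrium S1 binding IC50s and allosteric
potencies (dissociation-rate IC50s) of citalopram enantiomers and the
high-affinity vestibule ligand Lu AF60097 on wild-type SERT, and the Lu
AF60097 allosteric potencies of S2-pocket mutants.  Allosteric potency is
reported separately for each pre-bound radioligand because it depends on the
identity of the orthosterically bound ligand.
"""

from __future__ import annotations

__all__ = [
    "WT_POTENCY",
    "MUTANT_AP_LU",
    "MUTANT_AP_LU_CENSORED",
    "FOLD_RELATION_INPUTS",
]

#: wild-type values per compound:
#: s1_ic50 — equilibrium inhibition of S-CIT binding (nM);
#: ap_scit — allosteric potency with pre-bound S-CIT (nM);
#: ap_imi  — allosteric potency with pre-bound imipramine (nM).
WT_POTENCY = {
    "S-CIT": {"s1_ic50": 5.4, "ap_scit": 5200.0, "ap_imi": 152000.0},
    "R-CIT": {"s1_ic50": 180.0, "ap_scit": 21500.0, "ap_imi": 5340.0},
    "Lu AF60097": {"s1_ic50": 265.0, "ap_scit": 6500.0, "ap_imi": 31.0},
    "AE": {"s1_ic50": 1040.0, "ap_scit": 33800.0, "ap_imi": 120.0},
    "AF": {"s1_ic50": 79.0, "ap_scit": 10400.0, "ap_imi": 190.0},
}

#: Lu AF60097 allosteric potency (imipramine dissociation, nM) per construct.
MUTANT_AP_LU = {
    "WT": 31.0,
    "R104K": 630.0,
    "I179F": 440.0,
    "D328N": 54.0,
    "A331D": 9100.0,
    "L406E": 650.0,
    "A486E": 470.0,
    "A486E-K490A": 2400.0,
    "E494K": 8900.0,
    "E494Q": 170.0,
    "F556L": 330.0,
    "F556R": 10000.0,  # lower bound: no measurable potency in the tested range
}

#: constructs whose potency is a censored lower bound
MUTANT_AP_LU_CENSORED = {"F556R"}

#: additional reported potencies feeding the headline fold relations:
#: T497A and E494Q allosteric potencies of S-CIT (nM) per pre-bound ligand.
FOLD_RELATION_INPUTS = {
    "T497A_scit_ap_imi": 8800.0,    # S-CIT potency, pre-bound IMI, T497A
    "E494Q_scit_ap_scit": 64800.0,  # S-CIT potency, pre-bound S-CIT, E494Q
}
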