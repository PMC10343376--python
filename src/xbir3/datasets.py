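"""Published XIAP-BIR3 benchmark tables used as pipeline inputs.

These are small experimental/literature inputs, not computed results:
fluorescence-polarization IC50s for the four synthetic-ligand complexes
(PDB 5C7C, 5M6M, 5OQW, 5M6L) and the docked Smac AVPI tetrapeptide;
trajectory-averaged MM-PBSA estimates from 50-ns runs of those complexes
under the four force-field parametrization variants (plain, HMR, WYF,
HMR+WYF, each without entropy and with NM or IE entropy); and the
confusion counts of the five pharmacophore screening runs against the
173-active / 5417-inactive test chemolibrary.
"""
from __future__ import annotations

import pandas as pd

#: The four synthetic-ligand complexes, in benchmark order.
SYNTHETIC_COMPLEXES = ("5C7C", "5M6M", "5OQW", "5M6L")

#: Experimental affinities: IC50 (nM) and the ΔGexp (kcal/mol) as tabulated
#: in the source study (the AVPI row is knowingly inconsistent with the
#: RT·ln(IC50) conversion and is flagged downstream).
AFFINITY_TABLE = pd.DataFrame(
    [("5C7C", 5500.0, -7.29),
     ("5M6M", 44.0, -10.20),
     ("5OQW", 40.0, -10.26),
     ("5M6L", 5.1, -11.49),
     ("AVPI", 320.0, -8.91)],
    columns=["complex_id", "ic50_nM", "dg_exp_published"],
).set_index("complex_id")

#: Trajectory-averaged ΔG_MM-PBSA (kcal/mol, mean over snapshots) per
#: parametrization; "plain" = no additional parametrization.  Suffixes
#: _nm/_ie carry the normal-mode / interaction-entropy variants.
MMPBSA_TABLE = pd.DataFrame(
    {
        "plain":       [-36.5, -35.6, -46.2, -43.5, -46.2],
        "hmr":         [-37.4, -43.0, -43.9, -44.7, -39.5],
        "wyf":         [-30.5, -35.8, -46.8, -45.1, -47.5],
        "hmr_wyf":     [-34.4, -40.3, -45.4, -47.4, -38.2],
        "plain_nm":    [-25.6, -18.7, -29.9, -27.9, -28.7],
        "plain_ie":    [-10.9, -8.9, -28.0, -24.2, -33.2],
        "hmr_nm":      [-26.5, -27.5, -27.0, -29.2, -23.0],
        "hmr_ie":      [-17.6, -24.9, -24.2, -25.6, -22.8],
        "wyf_nm":      [-18.3, -17.7, -30.8, -28.8, -32.2],
        "wyf_ie":      [-17.5, -4.6, -34.0, -30.0, -31.7],
        "hmr_wyf_nm":  [-23.7, -23.5, -30.1, -32.3, -21.0],
        "hmr_wyf_ie":  [-8.1, -12.1, -25.8, -26.1, -19.5],
    },
    index=["5C7C", "5M6M", "5OQW", "5M6L", "AVPI"],
)

#: Test chemolibrary composition (pIC50 > 6 active, < 4.5 inactive with
#: DUD-E decoys; the 4.5–6 band excluded).
LIBRARY_N_ACTIVE = 173
LIBRARY_N_INACTIVE = 5417
LIBRARY_N_EXCLUDED = 96
LIBRARY_TOTAL = LIBRARY_N_ACTIVE + LIBRARY_N_INACTIVE  # D = 5590

#: Confusion counts of the published screening runs: pharmacophore model
#: number, allowed feature omissions, true positives (of 173 actives) and
#: true negatives (of 5417 inactives).
SCREENING_COUNTS = pd.DataFrame(
    [(1, 0, 5, 5417), (1, 1, 53, 5413),
     (2, 0, 7, 5417), (2, 1, 97, 5411),
     (3, 0, 7, 5417), (3, 1, 96, 5155),
     (4, 0, 17, 5416), (4, 1, 134, 5056),
     (5, 0, 136, 5338)],
    columns=["model", "omissions", "tp", "tn"],
)


def affinity_records(include_avpi: bool = False):
    """AffinityRecords for the benchmark complexes (IC50 in nM → mol/L).

    The AVPI tetrapeptide is excluded by default: correlation against the
    synthetic-ligand series is the primary benchmark, and its tabulated
    ΔGexp is inconsistent with the conversion (flagged when included).
    """
    from .bench import AffinityRecord
    ids = list(SYNTHETIC_COMPLEXES) + (["AVPI"] if include_avpi else [])
    return [AffinityRecord.from_value(cid, float(AFFINITY_TABLE.loc[cid, "ic50_nM"]), "nM")
            for cid in ids]
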