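"""Small published reference datasets bundled for validation and examples.

``PFAM_TM_BENCHMARK`` lists the TM helices embedded in 15 problematic Pfam
domain models (10 single-TM and 5 two-TM models), each with the published
complexity, hydrophobicity and z-score values.  They are the canonical
worked examples for the measures and the classifier: a correct
implementation reproduces every printed (x_c, x_phi) pair to the printed
two decimals.

``OCCURRENCE_EXPECTED_SIMPLE`` gives the published expected number of
simple TM helices per protein as a function of the protein's TM count
(1..15), at the two thresholds f = 1.282 and f = 1.645.  A zero-intercept
regression of these columns on the TM count yields slopes 0.218 and 0.112.
"""

from __future__ import annotations

from typing import NamedTuple


class BenchmarkTM(NamedTuple):
    domain: str
    sequence: str
    x_c: float
    x_phi: float
    z: float


#: (domain model, TM sequence, published x_c, x_phi, z); two-TM models
#: contribute two entries.
PFAM_TM_BENCHMARK: list[BenchmarkTM] = [
    BenchmarkTM("Herpes_glycop_D", "VIIGIVVLALLIGAIIVGVVYY", 1.20, 4.72, -19.34),
    BenchmarkTM("CDC50", "PFLGIAYLVVGGLCLVLGIVFLI", 1.66, 2.78, -7.37),
    BenchmarkTM("Cation_ATPase_N", "DPLVLLLLAAAIISALDFVLGG", 1.68, 2.38, -6.83),
    BenchmarkTM("GSPII_F", "LLLIVALLILLLLLAILLP", 0.55, 10.89, -53.23),
    BenchmarkTM("PAP2", "LLGLLLLLLALLVGLSRVY", 1.23, 4.48, -18.43),
    BenchmarkTM("PAP2", "LAGALLGALIAALVLLFVR", 1.44, 2.35, -11.49),
    BenchmarkTM("HCV_NS4b", "RVLVDVLGGYEAAVNAASLT", 2.50, 4.98, 3.50),
    BenchmarkTM("HCV_NS4b", "DLVNLLPALLSPGASVVGVALALI", 2.14, 1.45, -1.08),
    BenchmarkTM("PIG-P", "GFVLYILSQLAFILYLLWAF", 2.19, 5.77, -3.99),
    BenchmarkTM("PIG-P", "YWALAIPIYLLVALIFGYVVYFLY", 1.85, 5.35, -6.72),
    BenchmarkTM("EMP24_GP25L", "WWSIIQLLVLVGVSVFQVYYL", 1.71, 4.83, -8.09),
    BenchmarkTM("PTPLA", "YTLFIVLYPLGVTSELLTVY", 2.34, 2.87, -0.79),
    BenchmarkTM("PTPLA", "LIIALMLIYIPGFYQLYSH", 2.47, 3.28, -0.99),
    BenchmarkTM("Lamp", "LIPIAVGAALAGLVLIVLIAYLIG", 1.44, 3.50, -12.34),
    BenchmarkTM("MttA_Hcf106", "IGIPELLIILVVALLLFGP", 1.20, 5.42, -20.07),
    BenchmarkTM("HAMP", "LLLVLLIALLLALLLALLL", 0.73, 10.01, -43.85),
    BenchmarkTM("CorA", "LLTVGTTIFAPLTLIAGIYGM", 2.36, 1.70, -0.25),
    BenchmarkTM("CorA", "YGYPLVLGLMAILAIVLFLIILSYF", 1.65, 7.03, -11.97),
    BenchmarkTM("Vpu", "IIGLIALIVALIILAIVVWTIVI", 1.04, 8.09, -28.92),
    BenchmarkTM("RAMP", "VLLPLIVVPITLTLLLTALVVW", 1.31, 8.50, -21.96),
]

SINGLE_TM_DOMAINS = [
    "Herpes_glycop_D", "CDC50", "Cation_ATPase_N", "GSPII_F", "EMP24_GP25L",
    "Lamp", "MttA_Hcf106", "HAMP", "Vpu", "RAMP",
]
TWO_TM_DOMAINS = ["PAP2", "HCV_NS4b", "PIG-P", "PTPLA", "CorA"]

#: TM count (1..15) -> expected number of simple helices per protein, at the
#: z thresholds corresponding to f = 1.282 and f = 1.645.
OCCURRENCE_EXPECTED_SIMPLE: dict[str, list[float]] = {
    "n_tm": list(range(1, 16)),
    "f_1.282": [0.58, 0.80, 0.95, 1.07, 1.28, 1.41, 1.54, 1.87,
                2.18, 2.33, 2.29, 2.30, 2.56, 3.03, 3.26],
    "f_1.645": [0.42, 0.51, 0.55, 0.57, 0.70, 0.75, 0.78, 0.97,
                1.15, 1.16, 1.10, 1.15, 1.25, 1.55, 1.79],
}
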