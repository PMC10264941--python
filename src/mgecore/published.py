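"""Published worked-example comparison tables for *Halobacterium salinarum*.

Core-sequence comparison tables from the published genome comparison of the
*Hbt. salinarum* strains 63-R2, NRC-1, R1 and 91-R6 (chromosomes and the
plasmids pHcu235/pHS3, pHcu43/pHS4, pHcu190/pNRC100/pHS1): HSP coordinates
with their raw match/total/gap counts exactly as printed.  These serve as
input data for recomputing the derived quantities — truncated identity
cells, break lengths and overlap bookkeeping, cross-comparison event
deduplication, aggregate identity — from the package's own operations.

Row tuples: (tag, q_start, q_end, s_start, s_end, match, total, gaps).
"""

from __future__ import annotations

from .align import HSP

# 63-R2 core chromosome vs R1 core chromosome
CHROMOSOME_63R2_VS_R1 = [
    ("R_HSP1", 1, 170_773, 1, 170_773, 170_772, 170_773, 0),
    ("R_HSP2", 180_250, 589_134, 170_766, 579_649, 408_881, 408_885, 1),
    ("R_HSP3", 589_122, 1_095_986, 579_679, 1_086_558, 506_862, 506_880, 17),
    ("R_HSP4", 1_095_987, 1_861_458, 1_086_521, 1_852_001, 765_470, 765_481, 9),
    ("R_HSP5", 1_861_563, 1_997_337, 1_851_973, 1_987_747, 135_775, 135_775, 0),
]
LEN_63R2_CORE_R = (1_997_337, 1_987_747)  # (query, subject) core lengths

# 63-R2 core chromosome vs NRC-1 core chromosome
CHROMOSOME_63R2_VS_NRC1 = [
    ("N_HSP1", 1, 589_134, 1, 589_132, 589_128, 589_134, 2),
    ("N_HSP2", 589_122, 1_095_986, 589_162, 1_096_040, 506_858, 506_880, 18),
    ("N_HSP3", 1_095_987, 1_613_654, 1_096_003, 1_613_679, 517_642, 517_677, 9),
    ("N_HSP4", 1_613_819, 1_997_337, 1_613_421, 1_996_939, 383_517, 383_519, 0),
]
LEN_63R2_CORE_N = (1_997_337, 1_996_939)

# plasmid pHcu235 (63-R2) vs pHS3 (R1), core sequences
PHCU235_VS_PHS3 = [
    ("pHcu235_HSP1", 1, 210_501, 1, 210_501, 210_501, 210_501, 0),
    ("pHcu235_HSP2", 209_953, 212_491, 254_718, 257_256, 2_539, 2_539, 0),
    ("pHcu235_HSP3", 212_492, 230_601, 264_820, 282_929, 18_110, 18_110, 0),
]
LEN_PHCU235 = (230_601, 282_929)

# plasmid pHcu43 (63-R2) vs pHS4 (R1), core sequences
PHCU43_VS_PHS4 = [
    ("pHcu43_HSP1", 1, 39_479, 1, 39_481, 39_440, 39_483, 6),
]
LEN_PHCU43 = (39_479, 39_481)

# plasmid pHcu190 (63-R2) vs pNRC100 (NRC-1), core sequences
PHCU190_VS_PNRC100 = [
    ("N_pHcu190_HSP1", 1, 183_605, 1, 183_604, 183_597, 183_605, 1),
]
LEN_PHCU190_N = (183_605, 183_604)

# plasmid pHcu190 (63-R2) vs pHS1 (R1), core sequences
PHCU190_VS_PHS1 = [
    ("R_pHcu190_HSP1", 1, 72_155, 1, 72_155, 72_155, 72_155, 0),
    ("R_pHcu190_HSP2", 76_682, 125_134, 91_520, 139_972, 48_433, 48_453, 0),
]
LEN_PHCU190_R = (183_605, 141_861)

# pHcu229 vs pHS2 / pNRC200 identity cells (their tilings wrap the circular
# subject across its origin, so only the per-HSP counts are usable here)
PHCU229_IDENTITY_CELLS = [
    ("R_pHcu229_HSP1", 67_159, 67_160, 0),
    ("R_pHcu229_HSP2", 28_434, 28_434, 0),
    ("R_pHcu229_HSP3", 55_440, 55_440, 0),
    ("N_pHcu229_HSP1", 31_107, 31_107, 0),
    ("N_pHcu229_HSP2", 5_483, 5_483, 0),
    ("N_pHcu229_HSP3", 61_062, 61_063, 1),
]

# 38 HSPs of the 63-R2 vs 91-R6 core chromosome comparison, as summed in the
# publication: total aligned bp and identical bp
CHROMOSOME_63R2_VS_91R6_SUMS = (1_850_787, 1_844_079)


def as_hsps(rows: list[tuple]) -> list[HSP]:
    """Printed table rows as HSP objects (plus strand, counts as printed)."""
    return [
        HSP(q_start=qs, q_end=qe, s_start=ss, s_end=se, strand="+",
            match_bases=m, total_columns=t, gap_chars=g)
        for (_tag, qs, qe, ss, se, m, t, g) in rows
    ]
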