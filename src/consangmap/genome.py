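"""GRCh37 chromosome constants used as the default coordinate frame.

Physical autosome lengths (bp) follow the GRCh37/hg19 assembly. The default
genetic map assumes a uniform 1 cM per Mb, so a chromosome's map length in
centimorgans equals its physical length in megabases; callers can override
this with their own map.
"""

from __future__ import annotations

#: GRCh37 autosome lengths in base pairs (chromosomes "1".."22").
GRCH37_AUTOSOME_BP: dict[str, int] = {
    "1": 249_250_621,
    "2": 243_199_373,
    "3": 198_022_430,
    "4": 191_154_276,
    "5": 180_915_260,
    "6": 171_115_067,
    "7": 159_138_663,
    "8": 146_364_022,
    "9": 141_213_431,
    "10": 135_534_747,
    "11": 135_006_516,
    "12": 133_851_895,
    "13": 115_169_878,
    "14": 107_349_540,
    "15": 102_531_392,
    "16": 90_354_753,
    "17": 81_195_210,
    "18": 78_077_248,
    "19": 59_128_983,
    "20": 63_025_520,
    "21": 48_129_895,
    "22": 51_304_566,
}

#: GRCh37 X chromosome length in base pairs.
GRCH37_X_BP: int = 155_270_560

#: GRCh37 X pseudoautosomal regions as 1-based inclusive (start, end) pairs.
#: Markers inside these intervals behave autosomally and must be excluded
#: from X-homozygosity sex checks.
GRCH37_X_PAR: tuple[tuple[int, int], ...] = (
    (60_001, 2_699_520),
    (154_931_044, 155_260_560),
)


def is_pseudoautosomal(bp: int) -> bool:
    """True if an X-chromosome position falls in PAR1 or PAR2 (GRCh37)."""
    return any(start <= bp <= end for start, end in GRCH37_X_PAR)
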