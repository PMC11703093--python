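"""PRDM9 zinc-finger array parsing and diversity statistics.

A C2H2 zinc finger is modelled as a 28-residue unit on the scaffold
X7-CXXC-X12-HXXXH (cysteines at unit positions 8 and 11, histidines at
24 and 28, 1-based). Arrays are tiled greedily left to right. The last
unit of an array frequently lacks the terminal histidine (degenerate,
probably non-functional); occasional 27-residue units missing one
residue are flagged short. Both are excluded from the positional
diversity profile by default.

Positional diversity is Gini-Simpson heterozygosity d_i = 1 - sum_a f_a^2
computed over the set of *unique* units (each distinct unit counted once,
regardless of how many alleles carry it); a frequency-weighted mode is
available. The DNA-binding ratio r is the share of total diversity at the
four residues contacting DNA (alpha-helix positions -1, +2, +3, +6; unit
positions 16, 18, 19, 22 in this frame).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np

UNIT_LEN = 28
CONTACT_POSITIONS = (16, 18, 19, 22)  # 1-based within the 28-mer

_FULL = re.compile(r".{7}C.{2}C.{12}H.{3}H")
_SHORT = re.compile(r".{7}C.{2}C.{11}H.{3}H")  # one residue missing
_DEGEN = re.compile(r".{7}C.{2}C.{12}H.{3}[^H]")  # terminal His lost

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ZfUnit:
    seq: str
    degenerate: bool = False
    short: bool = False
    allele: str | None = None
    index: int | None = None

    def is_profile_eligible(self) -> bool:
        return not self.degenerate and not self.short and len(self.seq) == UNIT_LEN


@dataclass
class ParsedArray:
    units: list[ZfUnit]
    prefix: str  # non-conforming leading residues
    suffix: str  # non-conforming trailing residues


def parse_zf_array(aa_seq: str, allele: str | None = None) -> ParsedArray:
    """Tile an amino-acid sequence into C2H2 units, greedily left to right.

    At each position a full 28-mer is tried first, then a 27-mer with one
    internal residue deleted (flagged short), then a trailing 28-mer whose
    final histidine is substituted (flagged degenerate, ends the array).
    """
    seq = aa_seq.strip().upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"non-amino-acid characters in array: {sorted(bad)}")
    m = _FULL.search(seq)
    if m is None:
        raise ValueError("no C2H2 unit found in sequence")
    start = m.start()
    units: list[ZfUnit] = []
    pos = start
    idx = 0
    while pos < len(seq):
        window = seq[pos:pos + UNIT_LEN]
        if _FULL.fullmatch(window):
            units.append(ZfUnit(window, allele=allele, index=idx))
            pos += UNIT_LEN
        elif _SHORT.fullmatch(seq[pos:pos + UNIT_LEN - 1]):
            units.append(ZfUnit(seq[pos:pos + UNIT_LEN - 1], short=True,
                                allele=allele, index=idx))
            pos += UNIT_LEN - 1
        elif len(window) == UNIT_LEN and _DEGEN.fullmatch(window):
            units.append(ZfUnit(window, degenerate=True, allele=allele, index=idx))
            pos += UNIT_LEN
            break
        else:
            break
        idx += 1
    return ParsedArray(units=units, prefix=seq[:start], suffix=seq[pos:])


@dataclass
class ZfAlleleSet:
    """Catalogued alleles: name -> ordered units, with carrier counts."""

    alleles: dict[str, list[ZfUnit]]
    sequences: dict[str, str]
    counts: dict[str, int]  # carrier chromosomes per allele
    species: str | None = None

    def frequencies(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {k: v / total for k, v in self.counts.items()}

    def unique_units(self, include_flagged: bool = False) -> list[ZfUnit]:
        seen: dict[str, ZfUnit] = {}
        for units in self.alleles.values():
            for u in units:
                if include_flagged or u.is_profile_eligible():
                    seen.setdefault(u.seq, u)
        return list(seen.values())

    def all_units(self, include_flagged: bool = False) -> list[ZfUnit]:
        out = []
        for units in self.alleles.values():
            out.extend(u for u in units
                       if include_flagged or u.is_profile_eligible())
        return out


def catalogue_alleles(
    observations: dict[str, list[str]] | list[tuple[str, str]],
    species: str | None = None,
) -> ZfAlleleSet:
    """Collapse observed ZF-array sequences into named alleles.

    ``observations`` maps individual -> haplotype sequences (two entries
    per diploid genotype), or is a flat list of (carrier, sequence) pairs.
    Any single-residue difference founds a new allele. Alleles are named
    Z01, Z02, ... by decreasing carrier count (ties: first seen).
    """
    if isinstance(observations, dict):
        pairs = [(ind, s) for ind, seqs in observations.items() for s in seqs]
    else:
        pairs = list(observations)
    if not pairs:
        raise ValueError("no arrays supplied")
    counts: Counter[str] = Counter()
    order: list[str] = []
    for _, seq in pairs:
        seq = seq.strip().upper()
        if seq not in counts:
            order.append(seq)
        counts[seq] += 1
    ranked = sorted(order, key=lambda s: (-counts[s], order.index(s)))
    alleles, sequences, ncounts = {}, {}, {}
    for i, seq in enumerate(ranked, start=1):
        name = f"Z{i:02d}"
        parsed = parse_zf_array(seq, allele=name)
        alleles[name] = parsed.units
        sequences[name] = seq
        ncounts[name] = counts[seq]
    return ZfAlleleSet(alleles=alleles, sequences=sequences, counts=ncounts,
                       species=species)


@dataclass
class DiversityProfile:
    """Per-position Gini-Simpson diversity over a set of ZF units."""

    d: np.ndarray  # length 28
    contact_positions: tuple[int, ...] = CONTACT_POSITIONS
    n_units: int = 0


def position_diversity(
    units: list[ZfUnit] | ZfAlleleSet,
    unique: bool = True,
    include_flagged: bool = False,
) -> DiversityProfile:
    """Diversity d_i = 1 - sum_a f_a^2 at each of the 28 unit positions.

    With ``unique`` (the default) each distinct unit sequence counts once;
    otherwise every unit occurrence across alleles contributes.
    """
    if isinstance(units, ZfAlleleSet):
        units = (units.unique_units(include_flagged) if unique
                 else units.all_units(include_flagged))
    else:
        units = [u for u in units if include_flagged or u.is_profile_eligible()]
        if unique:
            units = list({u.seq: u for u in units}.values())
    seqs = [u.seq for u in units if len(u.seq) == UNIT_LEN]
    if len(seqs) < 2:
        raise ValueError("need at least 2 full-length units")
    mat = np.array([list(s) for s in seqs])
    d = np.empty(UNIT_LEN)
    for i in range(UNIT_LEN):
        _, cnt = np.unique(mat[:, i], return_counts=True)
        f = cnt / cnt.sum()
        d[i] = 1.0 - float((f ** 2).sum())
    return DiversityProfile(d=d, n_units=len(seqs))


def dna_binding_ratio(
    profile: DiversityProfile,
    contact_positions: tuple[int, ...] | None = None,
) -> float:
    """r = sum of diversity at DNA-contact positions / sum over all 28.

    Undefined (raises) when the profile is flat zero.
    """
    pos = contact_positions or profile.contact_positions
    total = float(profile.d.sum())
    if total <= 0:
        raise ValueError("zero total diversity: ratio undefined")
    idx = np.asarray(pos, dtype=int) - 1
    if np.any(idx < 0) or np.any(idx >= UNIT_LEN):
        raise ValueError("contact positions must be 1-based within the 28-mer")
    return float(profile.d[idx].sum() / total)
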