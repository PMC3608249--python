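"""In-silico model of mass-spectrometric bisulfite methylation measurement.

The assay modelled here amplifies bisulfite-converted DNA with a T7-tagged
reverse primer, transcribes the reverse-complement strand to RNA, cleaves
the transcript base-specifically with RNase A (T reaction: cut 3' of every
U), and reads cleavage-fragment masses by MALDI-TOF.  On the cleaved
strand a methylated CpG appears as G where an unmethylated one appears as
A, shifting the fragment mass by 16 Da per methylated CpG; the relative
peak intensities of the mass ladder give the methylation fraction.

CpG sites sharing one cleavage fragment are reported jointly as a "CpG
unit"; distinct CpG fragments of indistinguishable mass are flagged for
downstream averaging, and CpG fragments colliding with CpG-free fragments
are flagged unresolvable and dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AmpliconDef",
    "Fragment",
    "CpGUnitDef",
    "RESIDUE_MASS",
    "TERMINAL_WATER",
    "METHYL_SHIFT",
    "bisulfite_convert",
    "reverse_transcript",
    "cleave_transcript",
    "cleave_fragments",
    "fragment_mass",
    "map_cpg_units",
    "quantify_unit",
    "simulate_measurement",
]

# Average ribonucleotide residue masses (Da); a terminal water is added
# once per fragment.  The contract of record is the 16.00 Da per-CpG shift
# (G minus A) and mass additivity, not absolute calibrated masses.
RESIDUE_MASS = {"A": 329.21, "C": 305.18, "G": 345.21, "U": 306.17}
TERMINAL_WATER = 18.02
METHYL_SHIFT = RESIDUE_MASS["G"] - RESIDUE_MASS["A"]  # 16.00 Da

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_OF_DNA = str.maketrans("ACGT", "ACGU")


@dataclass(frozen=True)
class AmpliconDef:
    """A PCR amplicon with annotated CpG positions.

    ``cpg_positions`` are 0-based offsets of the CpG cytosines on the
    given strand of ``sequence``.
    """

    name: str
    sequence: str
    cpg_positions: tuple[int, ...]
    genomic_start: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty amplicon sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT characters in amplicon {self.name!r}: {sorted(bad)}")
        for p in self.cpg_positions:
            if self.sequence[p : p + 2] != "CG":
                raise ValueError(
                    f"cpg_position {p} of amplicon {self.name!r} is not at a CG dinucleotide"
                )


@dataclass(frozen=True)
class Fragment:
    """One RNase cleavage product of the transcript.

    ``span`` is the half-open [start, stop) interval on the transcript
    (5'->3'); fragments tile the transcript without gaps or overlaps.
    ``base_mass`` is the mass of the fully unmethylated state.
    """

    sequence: str
    span: tuple[int, int]
    cpg_count: int = 0

    @property
    def base_mass(self) -> float:
        return fragment_mass(self, 0)


@dataclass(frozen=True)
class CpGUnitDef:
    """A reporting unit: one or more CpG sites measured as a single value."""

    unit_label: str
    member_sites: tuple[int, ...]
    ambiguity_flag: str = "clean"  # clean | mass_collision | unresolvable

    def __post_init__(self) -> None:
        if not self.member_sites:
            raise ValueError("unit has no member sites")
        if list(self.member_sites) != sorted(self.member_sites):
            raise ValueError("member_sites must be sorted")
        if self.ambiguity_flag not in {"clean", "mass_collision", "unresolvable"}:
            raise ValueError(f"unknown ambiguity flag {self.ambiguity_flag!r}")


def bisulfite_convert(seq: str, methylated_cpg_offsets: Iterable[int] = ()) -> str:
    """Deaminate unmethylated cytosines: C -> T except protected CpG Cs.

    ``methylated_cpg_offsets`` must point at the C of a CG dinucleotide;
    those cytosines are retained, every other C reads as T.
    """
    meth = set(methylated_cpg_offsets)
    for o in meth:
        if seq[o : o + 2] != "CG":
            raise ValueError(f"offset {o} is not at a CpG cytosine")
    return "".join(
        "C" if (b == "C" and i in meth) else ("T" if b == "C" else b)
        for i, b in enumerate(seq)
    )


def reverse_transcript(dna: str) -> str:
    """RNA transcript of the reverse-complement strand (5'->3')."""
    return dna.translate(_DNA_COMPLEMENT)[::-1].translate(_RNA_OF_DNA)


def cleave_transcript(rna: str) -> list[Fragment]:
    """Cut a transcript 3' of every U (RNase A T reaction)."""
    frags: list[Fragment] = []
    start = 0
    for i, b in enumerate(rna):
        if b == "U":
            frags.append(Fragment(rna[start : i + 1], (start, i + 1)))
            start = i + 1
    if start < len(rna):
        frags.append(Fragment(rna[start:], (start, len(rna))))
    return frags


def cleave_fragments(converted_seq: str, cpg_offsets: Sequence[int] = ()) -> list[Fragment]:
    """Fragment the reverse transcript of a bisulfite-converted sequence.

    The transcript is the reverse complement of ``converted_seq`` in RNA
    alphabet, cut after every U.  Us arise only from As of the input, so
    the cleavage pattern does not depend on methylation state (methylation
    toggles A/G at CpG transcript positions, neither of which is cut).
    ``cpg_offsets`` (input-strand CpG C offsets) are used to annotate each
    fragment's CpG count.
    """
    if not converted_seq:
        raise ValueError("empty sequence")
    rna = reverse_transcript(converted_seq)
    n = len(converted_seq)
    # input-strand offset p maps to transcript position n - 1 - p
    cpg_t = sorted(n - 1 - p for p in cpg_offsets)
    out = []
    for frag in cleave_transcript(rna):
        lo, hi = frag.span
        k = sum(1 for t in cpg_t if lo <= t < hi)
        out.append(Fragment(frag.sequence, frag.span, cpg_count=k))
    return out


def fragment_mass(frag: Fragment, n_methylated: int = 0) -> float:
    """Fragment mass in Da with ``n_methylated`` of its CpGs methylated.

    The unmethylated mass sums average residue masses plus one terminal
    water; each methylated CpG substitutes G for A on the cleaved strand,
    adding exactly 16.00 Da.
    """
    if not 0 <= n_methylated <= frag.cpg_count:
        raise ValueError(
            f"n_methylated={n_methylated} outside [0, {frag.cpg_count}] for fragment"
        )
    base = sum(RESIDUE_MASS[b] for b in frag.sequence) + TERMINAL_WATER
    return base + METHYL_SHIFT * n_methylated


def map_cpg_units(amplicon: AmpliconDef, mass_resolution: float = 1.0) -> list[CpGUnitDef]:
    """Derive CpG reporting units and their ambiguity flags for an amplicon.

    Sites on one fragment form one unit.  Two CpG fragments whose full
    mass ladders coincide within ``mass_resolution`` are flagged
    ``mass_collision`` (averaged downstream); a CpG fragment any of whose
    methylated masses collides with a CpG-free fragment is flagged
    ``unresolvable`` (dropped downstream).
    """
    if mass_resolution <= 0:
        raise ValueError("mass_resolution must be positive")
    # conversion with no methylation; cleavage pattern is methylation-invariant
    converted = bisulfite_convert(amplicon.sequence, ())
    frags = cleave_fragments(converted, amplicon.cpg_positions)
    n = len(amplicon.sequence)
    site_t = {n - 1 - p: s for s, p in enumerate(sorted(amplicon.cpg_positions))}

    cpg_frags = [f for f in frags if f.cpg_count > 0]
    free_masses = [fragment_mass(f, 0) for f in frags if f.cpg_count == 0]

    def ladder(f: Fragment) -> list[float]:
        return [fragment_mass(f, k) for k in range(f.cpg_count + 1)]

    units: list[CpGUnitDef] = []
    for f in cpg_frags:
        lo, hi = f.span
        sites = tuple(sorted(s for t, s in site_t.items() if lo <= t < hi))
        flag = "clean"
        if any(
            abs(fragment_mass(f, k) - m) <= mass_resolution
            for k in range(1, f.cpg_count + 1)
            for m in free_masses
        ):
            flag = "unresolvable"
        else:
            for g in cpg_frags:
                if g is f or g.cpg_count != f.cpg_count:
                    continue
                if all(
                    abs(a - b) <= mass_resolution for a, b in zip(ladder(f), ladder(g))
                ):
                    flag = "mass_collision"
                    break
        label = "/".join(str(s + 1) for s in sites)
        units.append(CpGUnitDef(label, sites, flag))
    return sorted(units, key=lambda u: u.member_sites)


def quantify_unit(intensity_ladder: Sequence[float]) -> float:
    """Methylation fraction from the unit's mass-ladder peak intensities.

    ``intensity_ladder[k]`` is the signal of the k-methylated state,
    k = 0..K.  The fraction is sum(k * I_k) / (K * sum(I_k)); with all
    intensities zero the value is missing (NaN).
    """
    I = np.asarray(intensity_ladder, dtype=float)
    if I.ndim != 1 or len(I) < 2:
        raise ValueError("intensity ladder needs at least two states (K >= 1)")
    if np.any(I < 0):
        raise ValueError("negative intensity")
    total = I.sum()
    if total == 0:
        return float("nan")
    K = len(I) - 1
    return float(np.dot(np.arange(K + 1), I) / (K * total))


def simulate_measurement(
    true_fraction: float,
    noise_sd: float,
    replicates: int = 3,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Replicate measured fractions: truth plus Gaussian noise, clamped to [0, 1]."""
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = true_fraction + rng.normal(0.0, noise_sd, size=replicates) if noise_sd > 0 else np.full(replicates, true_fraction)
    return np.clip(vals, 0.0, 1.0)
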