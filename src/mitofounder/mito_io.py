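"""Reference handling, variant profiling against the rCRS, masking, heteroplasmy.

All coordinates are 1-based positions on the 16,569-bp revised Cambridge
Reference Sequence (rCRS) coordinate system, the standard for human mtDNA
nomenclature.  The molecule is circular: the control region wraps the origin
(16,024..16,569 joined to 1..576) while the coding region spans 577..16,023.

Variants are expressed relative to the reference.  Insertions are anchored at
the reference position *after which* bases are inserted (``309.1C`` style);
indels in homopolymer tracts are normalised to their 3'-most equivalent
placement, following forensic mtDNA nomenclature.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

RCRS_LENGTH = 16_569
CODING_START, CODING_END = 577, 16_023

_IUPAC = set("ACGTRYSWKMBDHVN")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input violates a domain invariant."""


def region_of(position: int) -> str:
    """Return ``"coding"`` or ``"control"`` for a 1-based rCRS position."""
    if not 1 <= position <= RCRS_LENGTH:
        raise ValidationError(f"position {position} outside 1..{RCRS_LENGTH}")
    return "coding" if CODING_START <= position <= CODING_END else "control"


@dataclass(frozen=True)
class ReferenceGenome:
    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _IUPAC
        if bad:
            raise ValidationError(f"non-IUPAC characters in reference: {sorted(bad)}")
        if self.name == "rCRS" and len(seq) != RCRS_LENGTH:
            raise ValidationError(
                f"reference named rCRS must be {RCRS_LENGTH} bp, got {len(seq)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """1-based access, wrapping modulo length when circular."""
        n = len(self.sequence)
        if self.circular:
            position = (position - 1) % n + 1
        if not 1 <= position <= n:
            raise ValidationError(f"position {position} outside linear reference")
        return self.sequence[position - 1]


@dataclass(frozen=True, order=True)
class Variant:
    """A single difference from the reference.

    ``ref_allele``/``alt_allele`` are nucleotide strings; ``"-"`` denotes a gap
    (so an insertion has ``ref_allele="-"`` and a deletion ``alt_allele="-"``).
    """

    position: int
    ref_allele: str
    alt_allele: str
    vclass: str = field(compare=False, default="")
    region: str = field(compare=False, default="")

    def __post_init__(self):
        if self.ref_allele == "-":
            vclass = "insertion"
        elif self.alt_allele == "-":
            vclass = "deletion"
        elif (self.ref_allele in _PURINES) == (self.alt_allele in _PURINES):
            vclass = "transition"
        else:
            vclass = "transversion"
        object.__setattr__(self, "vclass", vclass)
        object.__setattr__(self, "region", region_of(self.position))

    @property
    def is_indel(self) -> bool:
        return self.vclass in ("insertion", "deletion")

    def label(self) -> str:
        """PhyloTree-style token, e.g. ``A769G``, ``309.1C``, ``249d``."""
        if self.vclass == "insertion":
            return f"{self.position}.1{self.alt_allele}"
        if self.vclass == "deletion":
            return f"{self.position}d"
        return f"{self.ref_allele}{self.position}{self.alt_allele}"


@dataclass(frozen=True)
class VariantProfile:
    sample_id: str
    variants: tuple[Variant, ...]
    region_label: str = ""
    masked_removed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "variants", tuple(sorted(self.variants, key=lambda v: (v.position, v.alt_allele)))
        )

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def substitutions(self) -> tuple[Variant, ...]:
        return tuple(v for v in self.variants if not v.is_indel)

    def key(self) -> tuple:
        """Hashable haplotype identity (ignores sample_id)."""
        return tuple((v.position, v.ref_allele, v.alt_allele) for v in self.variants)


@dataclass(frozen=True)
class SiteMask:
    excluded_positions: frozenset[int]
    excluded_indel_positions: frozenset[int]
    excluded_alleles: frozenset[tuple[int, str]]

    def excludes(self, v: Variant) -> bool:
        if v.is_indel and v.position in self.excluded_indel_positions:
            return True
        if v.position in self.excluded_positions:
            return True
        return (v.position, v.alt_allele) in self.excluded_alleles


def default_mask() -> SiteMask:
    """The standard exclusion set: unreliable indel tracts at 309, 315,
    515–522 and 16193, the hypervariable hotspots 16182, 16183 and 16519,
    and the allele-specific entries 16182C / 16183C."""
    return SiteMask(
        excluded_positions=frozenset({16182, 16183, 16519}),
        excluded_indel_positions=frozenset({309, 315, 16193} | set(range(515, 523))),
        excluded_alleles=frozenset({(16182, "C"), (16183, "C")}),
    )


def load_reference(path: str | Path) -> ReferenceGenome:
    """Read a single-record FASTA reference.

    Raises FormatError for multi-record files and ValidationError for
    non-IUPAC characters or a wrong-length sequence named ``rCRS``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"expected exactly one record in {path}, found {len(records)}")
    rec = records[0]
    return ReferenceGenome(name=rec.id, sequence=str(rec.seq).upper())


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into {id: uppercase sequence}."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Variant calling


def _shift_insertion_3prime(ref: str, anchor: int, inserted: str) -> tuple[int, str]:
    """Slide an insertion (after 1-based ``anchor``) to its 3'-most placement.

    An insertion of ``s`` after position p is equivalent to inserting
    ``s[1:] + s[0]`` after p+1 whenever ref[p+1] == s[0].
    """
    s = inserted
    p = anchor
    while p + 1 <= len(ref) and ref[p] == s[0]:  # ref[p] is base at position p+1
        p += 1
        s = s[1:] + s[0]
    return p, s


def _shift_deletion_3prime(ref: str, start: int, length: int) -> int:
    """Slide a deletion of ref[start..start+length-1] (1-based) 3'-most."""
    p = start
    while p + length <= len(ref) and ref[p - 1] == ref[p + length - 1]:
        p += 1
    return p


def _variants_from_alignment(ref: str, ref_idx: np.ndarray, sample: str,
                             smp_idx: np.ndarray) -> list[Variant]:
    """Extract variants from aligned coordinate arrays (-1 marks a gap)."""
    variants: list[Variant] = []
    i = 0
    n = len(ref_idx)
    while i < n:
        r, s = ref_idx[i], smp_idx[i]
        if r >= 0 and s >= 0:
            rb, sb = ref[r], sample[s]
            if rb != sb and rb != "N" and sb != "N":
                variants.append(Variant(r + 1, rb, sb))
            i += 1
        elif r < 0:  # insertion relative to reference
            j = i
            ins = []
            while j < n and ref_idx[j] < 0:
                ins.append(sample[smp_idx[j]])
                j += 1
            anchor = int(ref_idx[i - 1]) + 1 if i > 0 else 0
            anchor, s_norm = _shift_insertion_3prime(ref, anchor, "".join(ins))
            for k, base in enumerate(s_norm):
                if base != "N":
                    variants.append(Variant(max(anchor, 1), "-", base))
            i = j
        else:  # deletion relative to reference
            j = i
            while j < n and smp_idx[j] < 0:
                j += 1
            start = int(ref_idx[i]) + 1
            length = j - i
            start = _shift_deletion_3prime(ref, start, length)
            for k in range(length):
                variants.append(Variant(start + k, ref[start + k - 1], "-"))
            i = j
    return variants


def call_variants(
    sample_seq: str,
    ref: ReferenceGenome,
    sample_id: str = "sample",
    region_label: str = "",
    min_identity: float = 0.95,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
) -> VariantProfile:
    """Profile a sample against the reference.

    Equal-length sequences are compared positionally; otherwise a global
    affine-gap alignment is performed first.  ``N`` bases never generate
    variants.  Raises ValidationError when alignment identity falls below
    ``min_identity`` (the sequence is then probably not a mitogenome).
    """
    sample_seq = sample_seq.upper()
    if not sample_seq:
        raise ValidationError("empty sample sequence")
    refseq = ref.sequence
    if len(sample_seq) == len(refseq):
        a = np.frombuffer(refseq.encode(), dtype="S1")
        b = np.frombuffer(sample_seq.encode(), dtype="S1")
        diff = np.nonzero((a != b) & (a != b"N") & (b != b"N"))[0]
        ident = 1.0 - len(diff) / len(refseq)
        if ident < min_identity:
            raise ValidationError(
                f"{sample_id}: identity {ident:.3f} below {min_identity}; not a mitogenome?"
            )
        variants = [Variant(int(i) + 1, refseq[i], sample_seq[i]) for i in diff]
        return VariantProfile(sample_id, tuple(variants), region_label)

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(refseq, sample_seq)[0]
    ref_idx, smp_idx = aln.indices  # -1 at gaps
    matches = sum(
        1
        for r, s in zip(ref_idx, smp_idx)
        if r >= 0 and s >= 0 and refseq[r] == sample_seq[s]
    )
    ident = matches / max(len(refseq), len(sample_seq))
    if ident < min_identity:
        raise ValidationError(
            f"{sample_id}: alignment identity {ident:.3f} below {min_identity}"
        )
    variants = _variants_from_alignment(refseq, ref_idx, sample_seq, smp_idx)
    return VariantProfile(sample_id, tuple(variants), region_label)


def apply_variants(profile: VariantProfile, ref: ReferenceGenome) -> str:
    """Reconstruct the sample sequence from a substitution-only profile."""
    seq = list(ref.sequence)
    for v in profile.variants:
        if v.is_indel:
            raise ValidationError("apply_variants supports substitution-only profiles")
        if seq[v.position - 1] != v.ref_allele:
            raise ValidationError(
                f"reference mismatch at {v.position}: expected {v.ref_allele}"
            )
        seq[v.position - 1] = v.alt_allele
    return "".join(seq)


def apply_mask(profile: VariantProfile, mask: SiteMask | None = None) -> VariantProfile:
    """Remove masked variants; idempotent; counts removals in masked_removed."""
    if mask is None:
        mask = default_mask()
    kept = tuple(v for v in profile.variants if not mask.excludes(v))
    removed = len(profile.variants) - len(kept)
    return VariantProfile(
        profile.sample_id, kept, profile.region_label, profile.masked_removed + removed
    )


# ---------------------------------------------------------------------------
# Heteroplasmy


@dataclass(frozen=True)
class AlleleObservation:
    position: int
    allele_frequencies: Mapping[str, float]


def call_heteroplasmy(obs: AlleleObservation, low: float = 0.31, high: float = 0.70) -> bool:
    """A position is heteroplasmic when every observed allele's frequency lies
    in the [31%, 70%] band (endpoints inclusive)."""
    freqs = {a: f for a, f in obs.allele_frequencies.items() if f > 0}
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"allele frequencies sum to {total}, not 1")
    if len(freqs) < 2:
        raise ValidationError("heteroplasmy call requires at least two observed alleles")
    return all(low <= f <= high for f in freqs.values())


# ---------------------------------------------------------------------------
# Tabular I/O

PROFILE_COLUMNS = ["sample_id", "position", "ref", "alt", "vclass", "region"]


def write_profiles_tsv(path: str | Path, profiles: Sequence[VariantProfile]) -> None:
    import pandas as pd

    rows = [
        {
            "sample_id": p.sample_id,
            "position": v.position,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "vclass": v.vclass,
            "region": v.region,
        }
        for p in sorted(profiles, key=lambda p: p.sample_id)
        for v in p.variants
    ]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: str | Path, region_labels: Mapping[str, str] | None = None
                      ) -> list[VariantProfile]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "ref": str, "alt": str})
    profiles = []
    for sid, grp in df.groupby("sample_id", sort=True):
        variants = tuple(
            Variant(int(r.position), r.ref, r.alt) for r in grp.itertuples()
        )
        label = (region_labels or {}).get(str(sid), "")
        profiles.append(VariantProfile(str(sid), variants, label))
    return profiles


def read_sample_sheet(path: str | Path) -> "pd.DataFrame":
    """TSV with columns sample_id, region_label and optionally haplogroup/path."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"sample sheet {path} lacks a sample_id column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id(s): {dups}")
    return df
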