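"""Mitochondrial coordinate system, gene map, and genetic code.

The human mitochondrial genome is a 16,569-bp circle numbered 1..16569 on the
L-strand in rCRS coordinates.  Position 3107 is the historical placeholder
('N') kept to preserve numbering; it is never a callable base.  The control
region wraps the origin (16024..16569 followed by 1..576); everything else is
"coding region" in the broad sense: rRNA, tRNA and protein genes plus a few
short intergenic spacers.  ND6 and eight tRNAs are read from the opposite
strand, so their codons/sequence are the reverse complement of the L-strand.

Translation uses the vertebrate mitochondrial genetic code (ATA=Met, TGA=Trp,
AGA/AGG=stop).

The packaged reference sequence is a synthetic rCRS-coordinate scaffold: a
real human mtDNA record remapped onto 16,569-bp rCRS numbering and patched to
the documented rCRS allele at every anchor locus used by the packaged tables
(see the FASTA header and docs/methods.md).  It is not the NCBI NC_012920.1
record, and positions away from anchored loci are not guaranteed to match it.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Iterator

import numpy as _np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

GENOME_LENGTH = 16569
PLACEHOLDER_NP = 3107
#: control region span on the circular genome (wraps the origin)
CONTROL_REGION = ((16024, 16569), (1, 576))

#: vertebrate mitochondrial genetic code (NCBI translation table 2)
MITO_CODON_TABLE = unambiguous_dna_by_id[2]

CATEGORIES = ("control_region", "rRNA", "tRNA", "protein_coding", "non_coding")


class MtPositionError(ValueError):
    """Raised for positions outside 1..16569 or at the 3107 placeholder."""


def check_np(np_: int) -> int:
    if isinstance(np_, bool) or not isinstance(np_, (int, _np.integer)):
        raise MtPositionError(f"position must be an integer, got {np_!r}")
    if not 1 <= np_ <= GENOME_LENGTH:
        raise MtPositionError(
            f"nucleotide position {np_} outside the mtgenome range 1..{GENOME_LENGTH}"
        )
    return np_


def circular_np(np_: int) -> int:
    """Wrap arbitrary integer coordinates onto 1..16569 (circular genome)."""
    return (np_ - 1) % GENOME_LENGTH + 1


@dataclass(frozen=True)
class GeneFeature:
    """One feature of the mitochondrial gene map.

    ``start``/``end`` are 1-based inclusive; a feature with start > end wraps
    the origin (only the control region does).  ``frame_start`` is the first
    position of codon 1 for protein genes; for the light-strand ND6 this is
    the *highest* coordinate since the gene is read toward lower positions.
    """

    name: str
    category: str
    start: int
    end: int
    strand: str = "H"
    frame_start: int | None = None

    def segments(self) -> tuple[tuple[int, int], ...]:
        if self.start <= self.end:
            return ((self.start, self.end),)
        return ((self.start, GENOME_LENGTH), (1, self.end))

    def positions(self) -> Iterator[int]:
        for lo, hi in self.segments():
            yield from range(lo, hi + 1)

    def contains(self, np_: int) -> bool:
        return any(lo <= np_ <= hi for lo, hi in self.segments())

    def __len__(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.segments())


@dataclass(frozen=True)
class SubstitutionEffect:
    """Annotation of a single-base substitution given in L-strand bases."""

    np: int
    ref: str
    alt: str
    region_category: str
    gene: str | None
    #: None exactly when the site is not protein-coding
    synonymous: bool | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    codon_number: int | None = None


def _load_packaged_text(name: str) -> str:
    return (resources.files("mthet") / "data" / name).read_text()


def load_gene_map() -> tuple[GeneFeature, ...]:
    feats = []
    lines = _load_packaged_text("gene_map.tsv").splitlines()
    header = lines[0].split("\t")
    assert header[:5] == ["name", "category", "start", "end", "strand"]
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        frame = int(parts[5]) if len(parts) > 5 and parts[5] else None
        feats.append(
            GeneFeature(parts[0], parts[1], int(parts[2]), int(parts[3]), parts[4], frame)
        )
    return tuple(feats)


class MtReference:
    """The 16,569-position reference genome plus its gene map."""

    def __init__(self, sequence: str, features: tuple[GeneFeature, ...]):
        sequence = sequence.upper()
        if len(sequence) != GENOME_LENGTH:
            raise ValueError(
                f"mitochondrial reference must be {GENOME_LENGTH} symbols, got {len(sequence)}"
            )
        if sequence[PLACEHOLDER_NP - 1] != "N":
            raise ValueError(f"position {PLACEHOLDER_NP} must be the 'N' placeholder")
        self.sequence = sequence
        self.features = features
        self._lookup = self._build_lookup(features)

    @staticmethod
    def _build_lookup(features: tuple[GeneFeature, ...]) -> list[GeneFeature]:
        lookup: list[GeneFeature | None] = [None] * (GENOME_LENGTH + 1)
        for feat in features:
            for np_ in feat.positions():
                if lookup[np_] is None:
                    lookup[np_] = feat
        # contiguous uncovered runs become non-coding spacer features
        np_ = 1
        while np_ <= GENOME_LENGTH:
            if lookup[np_] is None:
                lo = np_
                while np_ <= GENOME_LENGTH and lookup[np_] is None:
                    np_ += 1
                spacer = GeneFeature(f"NC_{lo}-{np_ - 1}", "non_coding", lo, np_ - 1)
                for p in range(lo, np_):
                    lookup[p] = spacer
            else:
                np_ += 1
        return lookup  # type: ignore[return-value]

    @classmethod
    @functools.cache
    def load(cls) -> "MtReference":
        """Load the packaged synthetic rCRS-coordinate scaffold and gene map."""
        lines = _load_packaged_text("rcrs_scaffold_synthetic.fasta").splitlines()
        seq = "".join(line.strip() for line in lines if not line.startswith(">"))
        return cls(seq, load_gene_map())

    # ------------------------------------------------------------------ bases
    def base(self, np_: int) -> str:
        """L-strand base at a position ('N' at the 3107 placeholder)."""
        return self.sequence[check_np(np_) - 1]

    def slice(self, start: int, length: int) -> str:
        """``length`` bases starting at ``start``, wrapping the origin."""
        return "".join(
            self.sequence[circular_np(start + k) - 1] for k in range(length)
        )

    # ---------------------------------------------------------------- regions
    def region_of(self, np_: int) -> GeneFeature:
        """The gene-map feature containing a position.

        Overlapping features (ATP8/ATP6, ND4L/ND4, two tRNA pairs) resolve to
        the feature appearing first in the map; intergenic spacers return a
        synthesized ``non_coding`` feature.
        """
        return self._lookup[check_np(np_)]

    def in_control_region(self, np_: int) -> bool:
        return self.region_of(np_).category == "control_region"

    # ------------------------------------------------------------ annotation
    def substitution_effect(self, np_: int, ref: str, alt: str) -> SubstitutionEffect:
        """Annotate an L-strand substitution ref>alt at a position.

        For protein genes the containing codon is translated with the
        vertebrate mitochondrial code; light-strand genes (ND6) are reverse
        complemented before codon extraction.  Amino acids are reported as
        3-letter codes.
        """
        check_np(np_)
        if np_ == PLACEHOLDER_NP:
            raise MtPositionError(
                f"position {PLACEHOLDER_NP} is the rCRS placeholder and cannot be annotated"
            )
        ref, alt = ref.upper(), alt.upper()
        if ref == alt:
            raise ValueError(f"ref and alt are both {ref!r} at np {np_}")
        if self.base(np_) != ref:
            raise ValueError(
                f"reference mismatch at np {np_}: genome has {self.base(np_)!r}, caller says {ref!r}"
            )
        feat = self.region_of(np_)
        gene = None if feat.category == "non_coding" else feat.name
        if feat.category != "protein_coding":
            return SubstitutionEffect(np_, ref, alt, feat.category, gene)

        frame = feat.frame_start
        if feat.strand == "H":
            offset = np_ - frame
            codon_start = frame + 3 * (offset // 3)
            codon = self.slice(codon_start, 3)
            pos_in_codon = offset % 3
            alt_codon = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1 :]
        else:
            # light strand: codon 1 begins at frame_start and runs toward
            # lower coordinates; coding sequence is the reverse complement
            offset = frame - np_
            top = frame - 3 * (offset // 3)
            codon = str(Seq(self.slice(top - 2, 3)).reverse_complement())
            pos_in_codon = offset % 3
            alt_b = str(Seq(alt).complement())
            alt_codon = codon[:pos_in_codon] + alt_b + codon[pos_in_codon + 1 :]
        ref_aa = _translate(codon)
        alt_aa = _translate(alt_codon)
        return SubstitutionEffect(
            np_,
            ref,
            alt,
            "protein_coding",
            gene,
            synonymous=(ref_aa == alt_aa),
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            codon_number=offset // 3 + 1,
        )

    # --------------------------------------------------------------- contexts
    def adjacent_sequence(self, np_: int, width: int = 3) -> str:
        """Flanking L-strand sequence with the site marked by ``*``.

        ``width`` bases each side; when a flank is a homopolymer the whole
        run is included.  Wraps the circular origin.
        """
        check_np(np_)
        seq = self.sequence

        def at(p: int) -> str:
            return seq[circular_np(p) - 1]

        left = [at(p) for p in range(np_ - width, np_)]
        if len(set(left)) == 1:
            p = np_ - width - 1
            while at(p) == left[0]:
                left.insert(0, at(p))
                p -= 1
        right = [at(p) for p in range(np_ + 1, np_ + width + 1)]
        if len(set(right)) == 1:
            p = np_ + width + 1
            while at(p) == right[0]:
                right.append(at(p))
                p += 1
        return "".join(left) + "*" + "".join(right)


def _translate(codon: str) -> str:
    aa = str(Seq(codon).translate(table=MITO_CODON_TABLE))
    return "Ter" if aa == "*" else seq3(aa)


def motif_flags(context: str) -> frozenset[str]:
    """Sequence-motif flags for a marked flanking context.

    Returns any of ``{"polyA", "polyC", "GGT"}``: a run of >=3 A (or C)
    abutting the marked site on either side, or the trinucleotide GGT
    immediately adjacent.
    """
    if context.count("*") != 1:
        raise ValueError(f"context must contain exactly one '*': {context!r}")
    left, right = context.split("*")
    if left and not set(left) <= set("ACGTN"):
        raise ValueError(f"malformed context {context!r}")
    if right and not set(right) <= set("ACGTN"):
        raise ValueError(f"malformed context {context!r}")
    flags = set()
    for base, flag in (("A", "polyA"), ("C", "polyC")):
        if left.endswith(base * 3) or right.startswith(base * 3):
            flags.add(flag)
    if left.endswith("GGT") or right.startswith("GGT"):
        flags.add("GGT")
    return frozenset(flags)
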