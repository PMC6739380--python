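"""Core domain types shared across the pipeline.

The pipeline is strictly biallelic: multiallelic VCF records are split on
input and every downstream operation sees one (chrom, pos, ref, alt) site at
a time. Coordinates are 1-based as in VCF; a single reference assembly is
assumed throughout.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

VariantKey = tuple  # (chrom: str, pos: int, ref: str, alt: str)


class GenotypeState(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        """True when at least one alternate allele is present (het or hom_alt)."""
        return self in (GenotypeState.HET, GenotypeState.HOM_ALT)


class Phenotype(enum.Enum):
    AFFECTED = "affected"
    NON_AFFECTED = "non_affected"


class Model(enum.Enum):
    """Inheritance model of a segregation call.

    recessive = shared homozygosity for the alternate allele within the
    phenotype group; dominant = shared carriage (>=1 alternate allele).
    """

    RECESSIVE = "recessive"
    DOMINANT = "dominant"


@dataclass(frozen=True, order=True)
class Variant:
    """One biallelic site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    known_id: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclass
class GenotypeCall:
    """One sample's genotype at one biallelic site.

    Missing FORMAT fields are carried as None, never as zeros.
    """

    sample_id: str
    state: GenotypeState
    depth: Optional[int] = None
    alt_depth: Optional[int] = None
    gq: Optional[float] = None

    def __post_init__(self):
        if self.depth is not None and self.alt_depth is not None and self.alt_depth > self.depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} exceeds depth {self.depth} for {self.sample_id}"
            )


@dataclass(frozen=True)
class PedigreeIndividual:
    individual_id: str
    family_id: str
    sex: str  # "M" | "F" | "U"
    phenotype: Phenotype


class Pedigree:
    """Families of siblings, each split into affected and non-affected members."""

    def __init__(self, individuals):
        self.families: dict[str, list[PedigreeIndividual]] = {}
        seen = set()
        for ind in individuals:
            if ind.individual_id in seen:
                raise ValueError(f"duplicate individual id {ind.individual_id!r}")
            seen.add(ind.individual_id)
            self.families.setdefault(ind.family_id, []).append(ind)

    def individuals(self) -> list[PedigreeIndividual]:
        return [ind for fam in self.families.values() for ind in fam]

    def sample_ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals()]

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family_ids(self) -> list[str]:
        return list(self.families)

    def group_members(self, family_id: str, group: Phenotype) -> list[PedigreeIndividual]:
        if family_id not in self.families:
            raise KeyError(f"family {family_id!r} absent from pedigree")
        return [ind for ind in self.families[family_id] if ind.phenotype == group]

    def validate_discordant_design(self, strict: bool = True) -> list[str]:
        """Every family must contain >=1 affected and >=1 non-affected sibling.

        Returns the list of offending family ids; raises in strict mode.
        """
        bad = []
        for fam_id, members in self.families.items():
            phenos = {m.phenotype for m in members}
            if phenos != {Phenotype.AFFECTED, Phenotype.NON_AFFECTED}:
                bad.append(fam_id)
        if bad and strict:
            raise ValueError(
                "families without both an affected and a non-affected member: "
                + ", ".join(sorted(bad))
            )
        return bad


@dataclass
class VariantAnnotation:
    """Per-variant annotation payload joined to a variant key.

    gmaf is the global minor allele frequency (<= 0.5 by definition);
    alt_pop_freq is the population frequency of the alternate allele and may
    exceed 0.5 when the reference carries the minor allele. Deleteriousness
    scores (CADD/DANN/PROVEAN) are opaque pass-through values.
    """

    key: VariantKey
    gene: str
    transcript_status: str = "confirmed"  # confirmed | unconfirmed
    region: str = "coding"  # coding | utr5 | utr3
    consequence_term: str = ""
    gmaf: Optional[float] = None
    alt_pop_freq: Optional[float] = None
    known_id: Optional[str] = None
    scores: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.gmaf is not None and not (0.0 <= self.gmaf <= 0.5):
            raise ValueError(f"gmaf must lie in [0, 0.5], got {self.gmaf}")

    @property
    def is_novel(self) -> bool:
        """Novel = absent from public catalogues: no GMAF and no known id."""
        return self.gmaf is None and self.known_id is None


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: tuple

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.set_id!r} contains duplicate genes")


class GeneSetCollection:
    def __init__(self, sets):
        self.sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.set_id in self.sets:
                raise ValueError(f"duplicate gene set id {s.set_id!r}")
            self.sets[s.set_id] = s

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id):
        return self.sets[set_id]

    def __eq__(self, other):
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


@dataclass(frozen=True)
class SegregationCall:
    """A variant segregating with phenotype under one inheritance model,
    confirmed in >=k of N families."""

    key: VariantKey
    gene: str
    model: Model
    group: Phenotype
    confirming_families: frozenset
    exclusive: Optional[bool] = None
    subthreshold: bool = False  # kept by same-gene rescue despite <k families


@dataclass(frozen=True)
class GroupSummaryRow:
    group: Phenotype
    model: Model
    n_genes: int
    n_variants: int
    n_immune_genes: int
    immune_pct: int  # nearest integer
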