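"""Alleles, genotypes, drive architectures and medfly sex determination.

The Mediterranean fruit fly (*Ceratitis capitata*) determines sex through the
Y-linked male-determining factor *MoY* and the autosomal master female gene
*transformer* (*tra*).  XY zygotes develop as males regardless of *tra*.  XX
zygotes develop as females only if they carry at least one functional *tra*
allele **and** received maternal *tra* product in the egg; losing either
condition converts them into viable, fertile XX males.  This malleability is
what the sex-conversion drive strategies modelled here exploit.

Target loci carry one of four allele classes: the wild-type sequence (the only
cleavable class), the drive construct itself (inserted into, and disrupting,
the target gene), and the two resistance classes produced by end-joining
repair — R1 indels that preserve target-gene function and R2 indels that
abolish it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum

__all__ = [
    "AlleleState",
    "LocusId",
    "Karyotype",
    "Sex",
    "DriveDesign",
    "Genotype",
    "Individual",
    "FEMALE_FERTILITY",
    "TRA_HOMING",
    "SSC",
    "DUAL_FERTILITY",
    "DESIGNS",
    "is_functional",
    "determine_sex",
    "determine_fertility",
]


class AlleleState(IntEnum):
    """State of one chromosome at a target locus."""

    WILD = 0
    DRIVE = 1
    R1 = 2
    R2 = 3


#: Allele classes that retain target-gene function.  The drive construct sits
#: inside the gene it homes into and therefore disrupts it, like an R2 indel.
FUNCTIONAL_STATES = frozenset({AlleleState.WILD, AlleleState.R1})

#: Only an intact wild-type target site can be recognised and cut by Cas9.
CLEAVABLE_STATES = frozenset({AlleleState.WILD})


class LocusId(str, Enum):
    """Autosomal loci the drive architectures act on.

    ``FERTILITY_1`` and ``FERTILITY_2`` are recessive female-fertility genes:
    females need at least one functional copy to reproduce, males are
    unaffected.  ``TRA`` is the master female-determining gene *transformer*.
    """

    FERTILITY_1 = "fertility_1"
    TRA = "tra"
    FERTILITY_2 = "fertility_2"


class Karyotype(str, Enum):
    XX = "XX"
    XY = "XY"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class DriveDesign:
    """A suppression-drive architecture.

    ``home_locus`` is the gene the construct is inserted into (and homes
    into); ``trans_target`` is an optional second gene cut in trans by an
    additional gRNA carried on the same construct (no homing there — the
    construct is not present at that locus, so cleavage can only be repaired
    by copying a resistance allele or by end joining).
    """

    name: str
    home_locus: LocusId
    trans_target: LocusId | None = None

    @property
    def loci(self) -> tuple[LocusId, ...]:
        """Loci explicitly modelled for this architecture."""
        if self.trans_target is None:
            return (self.home_locus,)
        return (self.home_locus, self.trans_target)

    @property
    def targets_tra(self) -> bool:
        return LocusId.TRA in self.loci

    @property
    def fertility_loci(self) -> tuple[LocusId, ...]:
        return tuple(
            l for l in self.loci if l in (LocusId.FERTILITY_1, LocusId.FERTILITY_2)
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Drive homing into a single recessive female-fertility gene.
FEMALE_FERTILITY = DriveDesign("female_fertility", LocusId.FERTILITY_1)
#: Drive homing directly into *transformer*.
TRA_HOMING = DriveDesign("tra_homing", LocusId.TRA)
#: Sterilising sex conversion: homing into a female-fertility gene while
#: cutting *transformer* in trans.
SSC = DriveDesign("ssc", LocusId.FERTILITY_1, LocusId.TRA)
#: Drive homing into one female-fertility gene while cutting a second,
#: independent female-fertility gene in trans.
DUAL_FERTILITY = DriveDesign("dual_fertility", LocusId.FERTILITY_1, LocusId.FERTILITY_2)

DESIGNS: dict[str, DriveDesign] = {
    d.name: d for d in (FEMALE_FERTILITY, TRA_HOMING, SSC, DUAL_FERTILITY)
}


def is_functional(allele: AlleleState) -> bool:
    """True iff the allele retains target-gene function (wild type or R1)."""
    return allele in FUNCTIONAL_STATES


AllelePair = tuple[AlleleState, AlleleState]

#: The fixed pair callers pass for *tra* when a design does not model it.
INTACT_TRA_PAIR: AllelePair = (AlleleState.WILD, AlleleState.WILD)


@dataclass
class Genotype:
    """Karyotype plus the (maternal, paternal) allele pair at each modelled locus."""

    karyotype: Karyotype
    alleles: dict[LocusId, AllelePair]

    def validate(self, design: DriveDesign) -> None:
        """Check structural invariants against the active design.

        Raises ``ValueError`` on a missing locus, a malformed pair, or a drive
        construct at a locus it cannot occupy (the construct physically sits
        at the home locus only; the trans target merely gets cut).
        """
        for locus in design.loci:
            if locus not in self.alleles:
                raise ValueError(f"genotype missing modelled locus {locus.value!r}")
            pair = self.alleles[locus]
            if len(pair) != 2:
                raise ValueError(f"locus {locus.value!r} needs exactly two alleles")
        for locus, pair in self.alleles.items():
            if AlleleState.DRIVE in pair and locus != design.home_locus:
                raise ValueError(
                    f"drive construct at {locus.value!r}, but design "
                    f"{design.name!r} homes into {design.home_locus.value!r}"
                )

    def tra_pair(self) -> AllelePair:
        """The *tra* allele pair, treating an unmodelled *tra* as intact."""
        return self.alleles.get(LocusId.TRA, INTACT_TRA_PAIR)

    def carries_drive(self) -> bool:
        return any(AlleleState.DRIVE in pair for pair in self.alleles.values())


def determine_sex(
    karyotype: Karyotype,
    tra_pair: AllelePair,
    maternal_tra_intact: bool,
) -> Sex:
    """Phenotypic sex from karyotype, zygotic *tra* genotype and maternal provision.

    XY is always male (*MoY* dominance).  An XX zygote is female only when
    both the maternal *tra* provision reached the egg and at least one of its
    own *tra* alleles is functional; otherwise it develops as a male.
    """
    if karyotype is Karyotype.XY:
        return Sex.MALE
    if not maternal_tra_intact:
        return Sex.MALE
    if not any(is_functional(a) for a in tra_pair):
        return Sex.MALE
    return Sex.FEMALE


def determine_fertility(sex: Sex, genotype: Genotype, design: DriveDesign) -> bool:
    """Fertility phenotype given an already-determined sex.

    Males are always fertile in this model (XX males are fertile in the
    medfly; intersexes, which arise experimentally from somatic mosaicism, are
    outside the model).  A female is sterile iff she lacks a functional allele
    at any female-fertility locus the design acts on — the fertility genes are
    recessive, so one functional copy suffices.
    """
    if sex is Sex.MALE:
        return True
    for locus in design.fertility_loci:
        pair = genotype.alleles[locus]
        if not any(is_functional(a) for a in pair):
            return False
    return True


@dataclass
class Individual:
    """One fly: genotype, maternal provision flag, and the derived phenotypes.

    ``sex`` and ``fertile`` are always computed from the genotype via
    :func:`determine_sex` / :func:`determine_fertility`; use :meth:`develop`
    rather than constructing instances by hand.
    """

    genotype: Genotype
    maternal_tra_intact: bool
    sex: Sex = field(init=False)
    fertile: bool = field(init=False)
    design: DriveDesign = field(repr=False, default=FEMALE_FERTILITY)

    def __post_init__(self) -> None:
        self.sex = determine_sex(
            self.genotype.karyotype, self.genotype.tra_pair(), self.maternal_tra_intact
        )
        self.fertile = determine_fertility(self.sex, self.genotype, self.design)

    @classmethod
    def develop(
        cls,
        genotype: Genotype,
        maternal_tra_intact: bool,
        design: DriveDesign,
    ) -> "Individual":
        genotype.validate(design)
        return cls(genotype=genotype, maternal_tra_intact=maternal_tra_intact, design=design)

    def carries_drive(self) -> bool:
        return self.genotype.carries_drive()
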