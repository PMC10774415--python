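"""Stochastic gamete formation under germline Cas9 activity.

A cleavage event at a wild-type target site is repaired either by
homology-directed repair (HDR) — copying whatever the homologous chromosome
currently carries, which is homing when the homolog carries the drive
construct, or resistance-allele copying when it carries R1/R2 — or by
non-homologous end joining (NHEJ), which writes a resistance indel (R2 with
probability ``r2_fraction``, R1 otherwise).  Only wild-type sites are
cleavable; the construct and both resistance classes have lost the gRNA
target site.

Three layers are provided:

* scalar operations on single allele pairs / individuals
  (:func:`resolve_germline`, :func:`form_gamete`, ...), the reference
  semantics;
* an exact analytic distribution (:func:`gamete_distribution`), obtained by
  enumerating every cleavage/repair outcome, used as an oracle for the
  stochastic paths;
* vectorised batch kernels (:func:`resolve_germline_batch`,
  :func:`sample_gametes_batch`) with identical semantics, used by the
  population simulator and the synthetic cross generator.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .genetics import (
    AllelePair,
    AlleleState,
    DriveDesign,
    Genotype,
    Individual,
    Karyotype,
    LocusId,
    Sex,
    is_functional,
)

__all__ = [
    "DriveParams",
    "Haplotype",
    "resolve_germline",
    "form_gamete",
    "gamete_distribution",
    "locus_gamete_distribution",
    "apply_maternal_deposition",
    "maternal_tra_provision",
    "resolve_germline_batch",
    "sample_gametes_batch",
    "sample_parent_gametes",
    "drive_transmission_probability",
]

_WILD = int(AlleleState.WILD)
_DRIVE = int(AlleleState.DRIVE)
_R1 = int(AlleleState.R1)
_R2 = int(AlleleState.R2)


@dataclass(frozen=True)
class DriveParams:
    """Rates governing drive activity.

    cleavage_rate : float in [0, 1]
        Probability ``c`` that a wild-type allele is cleaved in the germline
        of a construct carrier.
    hdr_rate : float in [0, 1]
        Probability ``h`` that a cleavage is repaired by HDR rather than NHEJ.
    r2_fraction : float in [0, 1]
        Probability that an NHEJ repair yields a non-functional R2 indel
        rather than a functional R1 indel.
    maternal_factor : float >= 0
        Proportionality constant ``k`` for deposited maternal Cas9: the
        embryonic cleavage probability is ``min(1, k * c)``.
    """

    cleavage_rate: float = 0.95
    hdr_rate: float = 0.95
    r2_fraction: float = 0.99
    maternal_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cleavage_rate", "hdr_rate", "r2_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.maternal_factor < 0.0:
            raise ValueError(
                f"maternal_factor must be non-negative, got {self.maternal_factor!r}"
            )

    @property
    def maternal_cleavage_rate(self) -> float:
        """Embryonic cleavage probability, clamped to [0, 1]."""
        return min(1.0, self.maternal_factor * self.cleavage_rate)


@dataclass(frozen=True)
class Haplotype:
    """One gamete: an allele per modelled locus plus the sex chromosome."""

    alleles: dict[LocusId, AlleleState]
    sex_chromosome: str  # "X" or "Y"


def _nhej(params: DriveParams, rng: np.random.Generator) -> AlleleState:
    return AlleleState.R2 if rng.random() < params.r2_fraction else AlleleState.R1


def resolve_germline(
    pair: AllelePair,
    can_home: bool,
    params: DriveParams,
    rng: np.random.Generator,
) -> AllelePair:
    """Resolve germline cleavage and repair at one locus of one meiosis.

    Each wild-type allele is cleaved independently with probability
    ``cleavage_rate``; cleaved alleles are then repaired in uniformly random
    order.  A cleaved allele repairs by HDR with probability ``hdr_rate``,
    copying the homolog's *current* state — unless the homolog is itself
    cleaved and not yet repaired, in which case no template exists and NHEJ
    applies.  The drive construct may only be copied where ``can_home`` is
    true (the design's home locus); everywhere else HDR can only restore wild
    type or copy a resistance allele.  Non-wild alleles are never altered.
    """
    states = [AlleleState(pair[0]), AlleleState(pair[1])]
    c = params.cleavage_rate
    cleaved = [s is AlleleState.WILD and rng.random() < c for s in states]
    if not any(cleaved):
        return (states[0], states[1])
    order = (0, 1) if rng.random() < 0.5 else (1, 0)
    repaired = [not cl for cl in cleaved]  # uncleaved alleles are valid templates
    for i in order:
        if not cleaved[i]:
            continue
        j = 1 - i
        template = repaired[j]
        copyable = states[j] is not AlleleState.DRIVE or can_home
        if template and copyable and rng.random() < params.hdr_rate:
            states[i] = states[j]
        else:
            states[i] = _nhej(params, rng)
        repaired[i] = True
    return (states[0], states[1])


def form_gamete(
    parent: Individual,
    design: DriveDesign,
    params: DriveParams,
    rng: np.random.Generator,
) -> Haplotype:
    """Draw one gamete from a fertile parent.

    Cleavage/repair is resolved independently at every modelled locus (the
    home locus may home; the trans target may only copy resistance alleles or
    end-join), then one allele per locus is sampled uniformly.  Each call is
    an independent meiosis; the parent is never mutated.  XY fathers transmit
    Y with probability 1/2; XX parents (mothers and converted XX males)
    always transmit X.
    """
    if not parent.fertile:
        raise ValueError("cannot form a gamete from a sterile parent")
    active = parent.carries_drive()
    alleles: dict[LocusId, AlleleState] = {}
    for locus in design.loci:
        pair = parent.genotype.alleles[locus]
        if active:
            pair = resolve_germline(pair, locus == design.home_locus, params, rng)
        alleles[locus] = pair[int(rng.random() < 0.5)]
    if parent.genotype.karyotype is Karyotype.XY and rng.random() < 0.5:
        chrom = "Y"
    else:
        chrom = "X"
    return Haplotype(alleles=alleles, sex_chromosome=chrom)


# ---------------------------------------------------------------------------
# Exact enumeration (oracle)
# ---------------------------------------------------------------------------


def _enumerate_repairs(states, cleaved, order, idx, weight, params, can_home, out):
    if idx == len(order):
        out[tuple(states)] += weight
        return
    i = order[idx]
    if not cleaved[i]:
        _enumerate_repairs(states, cleaved, order, idx + 1, weight, params, can_home, out)
        return
    j = 1 - i
    # homolog is a valid template if it was never cleaved or already repaired
    template = (not cleaved[j]) or (order.index(j) < idx)
    copyable = states[j] is not AlleleState.DRIVE or can_home
    h = params.hdr_rate if (template and copyable) else 0.0
    if h > 0.0:
        nxt = list(states)
        nxt[i] = states[j]
        _enumerate_repairs(nxt, cleaved, order, idx + 1, weight * h, params, can_home, out)
    for repair, p in ((AlleleState.R2, params.r2_fraction), (AlleleState.R1, 1 - params.r2_fraction)):
        if p <= 0.0:
            continue
        nxt = list(states)
        nxt[i] = repair
        _enumerate_repairs(
            nxt, cleaved, order, idx + 1, weight * (1 - h) * p, params, can_home, out
        )


def resolved_pair_distribution(
    pair: AllelePair, can_home: bool, params: DriveParams
) -> dict[AllelePair, float]:
    """Exact distribution of the post-germline allele pair at one locus."""
    c = params.cleavage_rate
    states = [AlleleState(pair[0]), AlleleState(pair[1])]
    out: dict[AllelePair, float] = defaultdict(float)
    options = [
        [(False, 1.0)] if s is not AlleleState.WILD else [(False, 1.0 - c), (True, c)]
        for s in states
    ]
    for ca, wa in options[0]:
        for cb, wb in options[1]:
            w = wa * wb
            if w <= 0.0:
                continue
            # both cleavage orders carry weight 1/2 each
            for order in ([0, 1], [1, 0]):
                _enumerate_repairs(states, (ca, cb), order, 0, w * 0.5, params, can_home, out)
    return dict(out)


def locus_gamete_distribution(
    pair: AllelePair, can_home: bool, params: DriveParams
) -> dict[AlleleState, float]:
    """Exact gamete allele distribution at one locus (sums to 1 within 1e-12)."""
    dist: dict[AlleleState, float] = defaultdict(float)
    for (a, b), w in resolved_pair_distribution(pair, can_home, params).items():
        dist[a] += 0.5 * w
        dist[b] += 0.5 * w
    return dict(dist)


def gamete_distribution(
    genotype: Genotype, design: DriveDesign, params: DriveParams
) -> dict[LocusId, dict[AlleleState, float]]:
    """Exact per-locus gamete distributions for a parent genotype.

    Loci are resolved independently, so the joint haplotype distribution is
    the product over loci.  Parents without the construct segregate
    Mendelian: their germline has no Cas9, so no cleavage occurs.
    """
    active = genotype.carries_drive()
    out: dict[LocusId, dict[AlleleState, float]] = {}
    for locus in design.loci:
        pair = genotype.alleles[locus]
        if active:
            out[locus] = locus_gamete_distribution(pair, locus == design.home_locus, params)
        else:
            dist: dict[AlleleState, float] = defaultdict(float)
            for a in pair:
                dist[AlleleState(a)] += 0.5
            out[locus] = dict(dist)
    return out


def drive_transmission_probability(params: DriveParams) -> float:
    """Closed-form P(gamete carries the construct) from a hemizygous parent.

    ``(1 + c*h) / 2``: the drive chromosome is always a candidate, and the
    wild-type homolog is converted with probability ``c*h``.
    """
    return (1.0 + params.cleavage_rate * params.hdr_rate) / 2.0


# ---------------------------------------------------------------------------
# Embryonic (maternal) effects
# ---------------------------------------------------------------------------


def apply_maternal_deposition(
    zygote: Genotype,
    mother_carries_construct: bool,
    design: DriveDesign,
    params: DriveParams,
    rng: np.random.Generator,
) -> Genotype:
    """Cleave zygotic wild-type alleles with maternally deposited Cas9.

    If the mother carries the construct, every wild-type allele at every
    targeted locus is independently cleaved with probability
    ``min(1, k * c)`` and repaired by NHEJ only — there is no homing in the
    embryo, so deposition can create resistance alleles but never the drive.
    """
    rate = params.maternal_cleavage_rate
    if not mother_carries_construct or rate <= 0.0:
        return zygote
    alleles = dict(zygote.alleles)
    for locus in design.loci:
        pair = list(alleles[locus])
        for k in (0, 1):
            if pair[k] is AlleleState.WILD and rng.random() < rate:
                pair[k] = _nhej(params, rng)
        alleles[locus] = (pair[0], pair[1])
    return Genotype(karyotype=zygote.karyotype, alleles=alleles)


def maternal_tra_provision(
    mother: Individual,
    design: DriveDesign,
    params: DriveParams,
    rng: np.random.Generator,
) -> bool:
    """Whether the egg receives maternal *tra* product.

    Cas9 from a *tra*-targeting construct can cleave the mother's own
    cleavable (wild-type) *tra* alleles in the nurse cells and oocyte; each is
    disrupted independently with probability ``cleavage_rate``, drawn fresh
    per offspring (nurse-cell mosaicism).  R1 alleles are cleavage-resistant
    and keep providing *tra*.  Provision fails iff no functional allele
    remains; mothers without a *tra*-targeting construct always provide.
    """
    if mother.sex is not Sex.FEMALE:
        raise ValueError("maternal tra provision is defined for mothers only")
    if not (design.targets_tra and mother.carries_drive()):
        return True
    remaining = 0
    for a in mother.genotype.tra_pair():
        if not is_functional(a):
            continue
        if a is AlleleState.WILD and rng.random() < params.cleavage_rate:
            continue  # disrupted in the ovary
        remaining += 1
    return remaining > 0


# ---------------------------------------------------------------------------
# Vectorised kernels
# ---------------------------------------------------------------------------


def resolve_germline_batch(
    pairs: np.ndarray,
    can_home: bool,
    params: DriveParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised :func:`resolve_germline` over an ``(n, 2)`` array of pairs.

    Semantics are identical to the scalar version; equality of the resulting
    distributions is asserted against :func:`locus_gamete_distribution` in the
    test suite.
    """
    pairs = np.asarray(pairs)
    n = pairs.shape[0]
    out = pairs.copy()
    if n == 0 or params.cleavage_rate <= 0.0:
        return out
    cleaved = (pairs == _WILD) & (rng.random((n, 2)) < params.cleavage_rate)
    ncl = cleaved.sum(axis=1)

    single = np.nonzero(ncl == 1)[0]
    if single.size:
        ci = np.argmax(cleaved[single], axis=1)
        homolog = pairs[single, 1 - ci]
        hdr = rng.random(single.size) < params.hdr_rate
        copy_ok = hdr & ((homolog != _DRIVE) | can_home)
        r2 = rng.random(single.size) < params.r2_fraction
        repaired = np.where(copy_ok, homolog, np.where(r2, _R2, _R1))
        out[single, ci] = repaired

    double = np.nonzero(ncl == 2)[0]
    if double.size:
        m = double.size
        first = rng.integers(0, 2, size=m)
        r2a = rng.random(m) < params.r2_fraction
        res_first = np.where(r2a, _R2, _R1)
        hdr = rng.random(m) < params.hdr_rate  # first repair is always a template
        r2b = rng.random(m) < params.r2_fraction
        res_second = np.where(hdr, res_first, np.where(r2b, _R2, _R1))
        out[double, first] = res_first
        out[double, 1 - first] = res_second
    return out


def sample_gametes_batch(
    pairs: np.ndarray,
    can_home: bool,
    params: DriveParams,
    rng: np.random.Generator,
    active: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one gamete allele per row of ``pairs`` after germline resolution.

    ``active`` masks rows whose parent actually carries the construct (and
    hence expresses Cas9); inactive rows segregate Mendelian.  With ``active``
    omitted every row is treated as drive-carrying.
    """
    pairs = np.asarray(pairs)
    n = pairs.shape[0]
    if active is None:
        resolved = resolve_germline_batch(pairs, can_home, params, rng)
    else:
        resolved = pairs.copy()
        idx = np.nonzero(active)[0]
        if idx.size:
            resolved[idx] = resolve_germline_batch(pairs[idx], can_home, params, rng)
    pick = rng.integers(0, 2, size=n)
    return resolved[np.arange(n), pick]


def sample_parent_gametes(
    parent: Individual,
    design: DriveDesign,
    params: DriveParams,
    n: int,
    rng: np.random.Generator,
) -> dict[LocusId, np.ndarray]:
    """``n`` independent meioses of one parent, as per-locus allele arrays.

    Vectorised counterpart of calling :func:`form_gamete` ``n`` times (sex
    chromosomes excluded); used for empirical-vs-analytic frequency checks.
    """
    if not parent.fertile:
        raise ValueError("cannot form gametes from a sterile parent")
    active = parent.carries_drive()
    out: dict[LocusId, np.ndarray] = {}
    for locus in design.loci:
        pair = np.array(
            [[int(a) for a in parent.genotype.alleles[locus]]], dtype=np.int8
        )
        tiled = np.repeat(pair, n, axis=0)
        if active:
            out[locus] = sample_gametes_batch(tiled, locus == design.home_locus, params, rng)
        else:
            out[locus] = tiled[np.arange(n), rng.integers(0, 2, size=n)]
    return out
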