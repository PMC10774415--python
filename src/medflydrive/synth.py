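"""Synthetic cross-progeny generator.

Emulates the homing-assay crosses: a hemizygous transgenic parent is mated to
wild-type or eye-mutant partners and the progeny are classified by construct
marker, eye-colour phenotype and (for *tra*-targeting designs) sex phenotype.
Progeny are drawn individual-by-individual from the same germline mechanics
the population simulator uses, so the tables come with known true parameters
and serve as end-to-end fixtures for the inference in
:mod:`medflydrive.crossstats`.

The scored eye gene is modelled as a generic recessive visible marker whose
transmission mechanics are identical to the construct's home locus (the
construct homes into the eye gene and disrupts it); an offspring is WHITE iff
both eye-locus alleles are non-functional, RED otherwise.  Somatic mosaicism
is outside the model, so MOSAIC and INTERSEX never occur in generated tables
(the readers still accept them in real-style data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .crossstats import CrossCounts
from .genetics import (
    AlleleState,
    DriveDesign,
    FEMALE_FERTILITY,
    Genotype,
    Individual,
    Karyotype,
    LocusId,
    SSC,
    Sex,
    determine_sex,
)
from .germline import DriveParams, sample_gametes_batch

__all__ = ["MateType", "CrossSpec", "simulate_cross", "generate_fixture_suite"]

_WILD = int(AlleleState.WILD)
_DRIVE = int(AlleleState.DRIVE)
_R1 = int(AlleleState.R1)
_R2 = int(AlleleState.R2)


class MateType(str, Enum):
    WILD_TYPE = "wild_type"
    EYE_MUTANT = "eye_mutant"


@dataclass(frozen=True)
class CrossSpec:
    """One synthetic cross: who carries the construct, whom they mate, and rates."""

    parent_sex: Sex
    mate_type: MateType
    params: DriveParams
    n_progeny: int
    seed: int
    design: DriveDesign = FEMALE_FERTILITY
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")

    def transgenic_parent(self) -> Individual:
        """Hemizygous construct carrier; raises if a requested female parent
        would in fact develop as male under the design's sex rules."""
        kary = Karyotype.XX if self.parent_sex is Sex.FEMALE else Karyotype.XY
        alleles = {
            locus: (AlleleState.WILD, AlleleState.WILD) for locus in self.design.loci
        }
        alleles[self.design.home_locus] = (AlleleState.WILD, AlleleState.DRIVE)
        geno = Genotype(karyotype=kary, alleles=alleles)
        sex = determine_sex(kary, geno.tra_pair(), True)
        if sex is not self.parent_sex:
            raise ValueError(
                f"a {self.parent_sex.value} transgenic parent is inconsistent with "
                f"design {self.design.name!r}: this genotype develops as {sex.value}"
            )
        return Individual.develop(geno, True, self.design)


def _mate_allele(mate_type: MateType, locus: LocusId, design: DriveDesign) -> int:
    # eye-mutant mates are homozygous for a disrupted (non-cleavable,
    # non-functional) allele at the scored eye gene, i.e. the home locus
    if mate_type is MateType.EYE_MUTANT and locus == design.home_locus:
        return _R2
    return _WILD


def simulate_cross(spec: CrossSpec) -> CrossCounts:
    """Draw ``n_progeny`` offspring of one cross and tabulate their phenotypes.

    The transgenic parent's gametes go through germline cleavage/repair; the
    mate segregates Mendelian.  When the transgenic parent is the mother, her
    deposited Cas9 cleaves zygotic wild-type alleles (NHEJ only) and — for
    *tra*-targeting designs — maternal *tra* provision is drawn per offspring.
    """
    design = spec.design
    params = spec.params
    parent = spec.transgenic_parent()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_progeny

    child: dict[LocusId, np.ndarray] = {}
    for locus in design.loci:
        pair = np.repeat(
            np.array([[int(a) for a in parent.genotype.alleles[locus]]], dtype=np.int8),
            n,
            axis=0,
        )
        tg = sample_gametes_batch(pair, locus == design.home_locus, params, rng)
        mg = np.full(n, _mate_allele(spec.mate_type, locus, design), dtype=np.int8)
        if spec.parent_sex is Sex.FEMALE:
            maternal, paternal = tg, mg
        else:
            maternal, paternal = mg, tg
        child[locus] = np.stack([maternal, paternal], axis=1)

    # the XY parent (transgenic father, or wild-type/mutant mate of a
    # transgenic mother) transmits Y with probability 1/2
    karyotype_y = rng.random(n) < 0.5

    mother_transgenic = spec.parent_sex is Sex.FEMALE
    if mother_transgenic and params.maternal_cleavage_rate > 0.0:
        rate = params.maternal_cleavage_rate
        for locus in design.loci:
            arr = child[locus]
            cut = (arr == _WILD) & (rng.random((n, 2)) < rate)
            if cut.any():
                r2 = rng.random((n, 2)) < params.r2_fraction
                arr[cut & r2] = _R2
                arr[cut & ~r2] = _R1

    if mother_transgenic and design.targets_tra:
        tra = parent.genotype.alleles[LocusId.TRA]
        n_wild = sum(1 for a in tra if a is AlleleState.WILD)
        has_r1 = any(a is AlleleState.R1 for a in tra)
        p_fail = 0.0 if has_r1 else params.cleavage_rate**n_wild
        intact = rng.random(n) >= p_fail
    else:
        intact = np.ones(n, dtype=bool)

    marker = np.where(
        (child[design.home_locus] == _DRIVE).any(axis=1), "POSITIVE", "NEGATIVE"
    )
    eye_arr = child[design.home_locus]
    functional = (eye_arr == _WILD) | (eye_arr == _R1)
    eye = np.where(functional.any(axis=1), "RED", "WHITE")

    cols = {"replicate": spec.replicate, "marker": marker, "eye_phenotype": eye}
    if design.targets_tra:
        tra_arr = child[LocusId.TRA]
        has_tra = ((tra_arr == _WILD) | (tra_arr == _R1)).any(axis=1)
        male = karyotype_y | ~intact | ~has_tra
        cols["sex_phenotype"] = np.where(male, "MALE", "FEMALE")
    else:
        cols["sex_phenotype"] = pd.NA

    df = (
        pd.DataFrame(cols)
        .groupby(["replicate", "marker", "sex_phenotype", "eye_phenotype"], dropna=False)
        .size()
        .reset_index(name="count")
    )
    return CrossCounts(
        df,
        parent_sex=spec.parent_sex.value,
        mate_type=spec.mate_type.value,
        true_params={
            "cleavage_rate": params.cleavage_rate,
            "hdr_rate": params.hdr_rate,
            "r2_fraction": params.r2_fraction,
            "maternal_factor": params.maternal_factor,
            "design": design.name,
            "parent_sex": spec.parent_sex.value,
            "mate_type": spec.mate_type.value,
            "n_progeny": spec.n_progeny,
        },
    )


def _fixture_specs(master_seed: int) -> list[tuple[str, CrossSpec]]:
    seeds = [
        int(ss.generate_state(1)[0] % (2**31))
        for ss in np.random.SeedSequence(master_seed).spawn(8)
    ]
    strong = DriveParams(cleavage_rate=0.9, hdr_rate=0.8, r2_fraction=1.0)
    weak = DriveParams(cleavage_rate=0.3, hdr_rate=0.5, r2_fraction=1.0)
    perfect = DriveParams(cleavage_rate=1.0, hdr_rate=1.0, r2_fraction=1.0)
    specs = [
        ("mother_mutant_strong", CrossSpec(Sex.FEMALE, MateType.EYE_MUTANT, strong, 5000, seeds[0])),
        ("father_mutant_strong", CrossSpec(Sex.MALE, MateType.EYE_MUTANT, strong, 5000, seeds[1])),
        ("mother_wildtype_strong", CrossSpec(Sex.FEMALE, MateType.WILD_TYPE, strong, 5000, seeds[2])),
        ("father_wildtype_strong", CrossSpec(Sex.MALE, MateType.WILD_TYPE, strong, 5000, seeds[3])),
        ("mother_mutant_weak", CrossSpec(Sex.FEMALE, MateType.EYE_MUTANT, weak, 5000, seeds[4])),
        ("father_mutant_weak", CrossSpec(Sex.MALE, MateType.EYE_MUTANT, weak, 5000, seeds[5])),
        ("ssc_mother_perfect", CrossSpec(Sex.FEMALE, MateType.WILD_TYPE, perfect, 5000, seeds[6], design=SSC)),
        ("ssc_father_strong", CrossSpec(Sex.MALE, MateType.WILD_TYPE, strong, 5000, seeds[7], design=SSC)),
    ]
    return specs


def generate_fixture_suite(seed: int, out_dir: str | Path) -> dict:
    """Write a deterministic suite of synthetic cross tables plus a manifest.

    The suite spans the experimental regimes: strong and weak drive activity,
    transgenic mothers versus fathers, eye-mutant versus wild-type mates, and
    sex-converting crosses.  The manifest records the true parameters of
    every file; identical seeds yield byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out_dir}: {exc}") from exc
    manifest: dict = {"seed": seed, "files": {}}
    for name, spec in _fixture_specs(seed):
        cc = simulate_cross(spec)
        path = out_dir / f"{name}.tsv"
        try:
            cc.to_tsv(path)
        except OSError as exc:
            raise OSError(f"failed writing fixture {path}: {exc}") from exc
        manifest["files"][name] = {"path": path.name, **(cc.true_params or {})}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
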