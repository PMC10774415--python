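# medflydrive

Stochastic modelling of CRISPR homing gene drives and genetic sex conversion
in the Mediterranean fruit fly (*Ceratitis capitata*), for researchers
designing or evaluating suppression-drive strategies in tephritid pests.

## The model

The medfly determines sex through the Y-linked male-determining factor *MoY*
and the autosomal master female gene *transformer* (*tra*): an XX zygote
develops as a female only if it carries a functional *tra* allele **and**
received maternal *tra* product in the egg; losing either converts it into a
viable, *fertile* XX male. This malleability allows drive architectures that
couple super-Mendelian inheritance to sex conversion.

The package simulates four suppression-drive architectures as an agent-based,
discrete-generation model:

* **female_fertility** — construct homes into a recessive female-fertility gene;
* **tra_homing** — construct homes directly into *tra*;
* **ssc** (*sterilising sex conversion*) — construct homes into a
  female-fertility gene while a second gRNA cuts *tra* in trans;
* **dual_fertility** — homes into one fertility gene, cuts a second in trans.

Germline mechanics per cleavable (wild-type) target allele of a construct
carrier: cleavage with probability *c*; repair by HDR with probability *h*
(homing the construct, or copying whatever the homolog carries), otherwise
NHEJ, which writes a non-functional **R2** indel with probability *r2* and a
functional **R1** indel otherwise. A hemizygote therefore transmits the
construct at rate

    T = (1 + c·h) / 2,

and the disrupted-site fraction among its non-carrier gametes is
*m* = *c*(1 − *h*)/(1 − *c·h*). Mothers carrying the construct additionally
deposit Cas9 into the embryo (cleavage probability min(1, *k·c*), NHEJ-only)
and — for *tra*-targeting designs — may lose maternal *tra* provision, in
which case **all** their progeny develop as males.

A release scenario starts 500 wild-type females, 250 wild-type males and 250
hemizygous drive males (construct allele frequency 12.5%) and runs up to 20
non-overlapping generations of constant census size; extinction is the first
generation without fertile females or fertile males. Parameter sweeps over
(*c*, *r2*, *h*) summarise extinction fraction and time to extinction per
grid point, and a LOESS-style local polynomial smoother turns the noisy grid
into a continuous extinction surface.

A cross-statistics module handles progeny count tables from homing assays
(transmission rates with Wilson score intervals, chi-square goodness of fit,
inversion of (T, m) into (c, h)), and a synthetic-cross generator produces
such tables with known true parameters for end-to-end validation.

## Worked example

```python
from medflydrive import (SSC, DriveParams, SimConfig, run_replicates,
                         summarize_replicates, infer_cleavage_hdr)

# invert published cross fractions: 85.6% transmission, 74.7% disrupted
# target sites among non-carrier progeny of transgenic females
c, h = infer_cleavage_hdr(0.856, 0.747)
print(f"inferred cleavage rate c = {c:.3f}, HDR rate h = {h:.3f}")

# 100 replicate releases of the sterilising sex-conversion drive
cfg = SimConfig(design=SSC, params=DriveParams(cleavage_rate=0.95, hdr_rate=0.95,
                                               r2_fraction=0.99), seed=42)
summary = summarize_replicates(run_replicates(cfg, 100))
print(f"extinction fraction: {summary.extinction_fraction:.2f}")
print(f"mean generations to extinction: {summary.mean_time_to_extinction:.1f}")
```

prints

```
inferred cleavage rate c = 0.927, HDR rate h = 0.768
extinction fraction: 0.44
mean generations to extinction: 13.7
```

The first line estimates the germline rates implied by the measured
female-germline cross: ~93% of wild-type chromosomes are cut and ~77% of cuts
are repaired by homing. The simulation lines show that at slightly higher
rates (c = h = 0.95) and an almost fully disruptive resistance spectrum
(r2 = 0.99) the SSC strategy eliminates 44% of 1000-fly populations within 20
generations, in a mean of ~14 generations; the same scenario with the plain
female-fertility drive yields no extinctions, illustrating SSC's tolerance of
functional resistance.

The same functionality is available from the shell:

```sh
medflydrive simulate --design ssc --cleavage 0.95 --hdr 0.95 --r2 0.99 \
    --generations 20 --reps 100 --seed 42 --out out/
medflydrive sweep --preset extinction-surface --design ssc --seed 7 --out sweep.tsv
medflydrive smooth --in sweep.tsv --span 0.75 --degree 2 --out surface.tsv
medflydrive synth-cross --parent father --mate eye-mutant --cleavage 0.9 \
    --hdr 0.8 --n 5000 --seed 11 --out fixtures/
medflydrive cross-stats --counts fixtures/cross.tsv --expected 0.5 --out stats.json
```

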