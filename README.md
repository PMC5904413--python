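# cascadescope

Specificity analysis of the *E. coli* type I-E CRISPR-Cas surveillance
complex (Cascade), built as a tested, reusable pipeline that runs
end-to-end on synthetic data with known ground truth.

Cascade presents a 32-nt crRNA spacer to double-stranded DNA. Binding
requires a 3-nt protospacer-adjacent motif (PAM; AAG is optimal,
CCG is dead) immediately 5′ of the protospacer on the nontarget strand,
plus base pairing that nucleates in the PAM-proximal *seed* region. Every
sixth spacer position (6, 12, 18, 24, 30) is flipped out of the duplex and
never pairs. The central quantitative result this package encodes and
measures: **as few as 5 bp of PAM-proximal pairing (with an AAG PAM)
suffice for Cascade binding, while interference and primed adaptation
require pairing beyond position 18** — so a cell tolerates hundreds of
inert off-target binding events without genome damage.

## What's in the box

| module | role |
| --- | --- |
| `duplex_model` | spacers, crRNAs, target sites, per-position match profiles (`L` = PAM-proximal contiguous match length, flipped positions never terminate it), PAM classes, and the binding/interference/priming outcome classifier calibrated on a 13-variant protospacer panel |
| `offtarget_scan` | exhaustive both-strand genome scanner for candidate sites, per-spacer census, BED6 output, and the 8-nt 3′-end RNA complementarity search |
| `chip_quant` | coverage normalization (reads per 100,000), a minimal threshold peak caller, 1-kb window maxima, replicate R² at peak centers, peak–site association, AAG fraction by enrichment rank |
| `motif_stats` | spacer-anchored match matrices over bound regions; exact Fisher test (positions 7–9 vs PAM class) and exact binomial test (position-6 enrichment), both by integer enumeration |
| `pooled_quant` | read assignment to variant references via minimal unique windows; ChIP enrichment vs the optimal variant; interference efficiency vs the dead-PAM variant; transformation-efficiency ratios; adaptation readouts |
| `synthetic_data` | random genomes, planted sites with controlled match profiles, Gaussian-pileup ChIP coverage, multinomial pooled counts — the ground truth every stage is tested against |

The `analysis/` directory holds the numbered drivers
(`01_simulate.py` … `05_variant_panel.py`) that run the whole pipeline and
write tables under `results/`. A thin `cascadescope` CLI exposes the same
stages (`simulate`, `scan`, `classify-panel`, `chip-quant`, `motif-stats`,
`pool-quant`).

## Worked example

```python
import numpy as np
from cascadescope import Spacer, classify_panel

rng = np.random.default_rng(11)
spacer = Spacer(id="sp8", sequence="".join(rng.choice(list("ACGT"), size=32)))
for label, site, prof, call in classify_panel(spacer):
    print(label, site.pam, prof.L, call.binding, call.interference, call.priming)
```

prints the 13-variant outcome table:

```
i    AAG 32 stable    detectable detectable
ii   CCG 32 none      none       none
iii  ATT 32 stable    detectable detectable
iv   AAG  0 stable    none       detectable
v    AAG  0 stable    none       detectable
vi   AAG  0 stable    none       detectable
vii  AAG  1 stable    detectable detectable
viii AAG  1 stable    detectable detectable
ix   AAG 24 stable    none       detectable
x    AAG 18 stable    none       none
xi   AAG  0 none      none       none
xii  AAG  0 none      none       none
xiii AAG  6 transient none       none
```

Variant x is the boundary case: a fully stable 18-bp duplex with neither
interference nor priming. Exactly four variants (iv, v, vi, ix) prime
without detectable interference.

Running the full analysis chain (`python analysis/01_simulate.py` through
`05_variant_panel.py`) on the default 220-kb simulated genome with 61
planted sites reports, among other things:

```
61 peaks; replicate R^2 at peak centers = 0.999
affinity vs peak-center coverage: Spearman rho = 0.991 (61/61 sites matched to peaks)
matches at 7-9: 2.32/3 for non-AAG (n=22) vs 1.05/3 for AAG (n=38); Fisher exact P = 4.20e-08
position-6 match fraction 0.42 (n=60) vs 0.25 by chance; binomial P = 3.42e-03
interference-positive at 3-SD threshold: ['i', 'iii', 'vii', 'viii'] (classifier: ['i', 'iii', 'vii', 'viii'])
```

i.e. sites with a suboptimal PAM compensate with matches at positions 7–9,
the flipped-out position 6 still shows match enrichment above chance, and
the pooled ±cas3 estimator recovers exactly the classifier's
interference-positive variants.

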