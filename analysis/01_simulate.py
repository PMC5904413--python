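"""Simulate the study system: a genome with planted Cascade sites and ChIP
coverage.

Builds a 220-kb random genome carrying one on-target protospacer (full match,
AAG PAM) and 60 off-target sites whose structure mirrors in vivo binding-site
statistics: every site keeps the 5-nt PAM-proximal seed; 41 sites have the
optimal AAG PAM with sparse matches at positions 7-9 (mean 1.2/3), 19 carry a
suboptimal PAM compensated by dense 7-9 matches (mean 2.2/3); position 6
matches at 45%.  Two replicate ChIP coverage tracks are then simulated from
the same affinity weights.

Writes results/sim/: genome.fa, spacer.fa, truth files, coverage TSVs.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from cascadescope.duplex_model import Spacer
from cascadescope import io as cio
from cascadescope import synthetic_data as synth

SEED = 11
GENOME_LENGTH = 220_000
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "sim")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    rng = np.random.default_rng(SEED)
    spacer = Spacer(id="sp8", sequence="".join(rng.choice(list("ACGT"), size=32)))

    specs, weights = synth.sample_offtarget_specs(
        spacer, genome_length=GENOME_LENGTH, n_sites=60, seed=SEED, min_spacing=3000
    )
    genome = {"chr": synth.make_genome(GENOME_LENGTH, 0.5, seed=SEED)}
    genome, truth = synth.plant_sites(genome, spacer, specs)
    truth.weights = weights
    truth.seed = SEED

    cio.write_fasta(genome, os.path.join(OUT, "genome.fa"))
    cio.write_fasta({spacer.id: spacer.sequence}, os.path.join(OUT, "spacer.fa"))
    synth.write_truth(truth, OUT)

    for rep, rep_seed in (("rep1", SEED + 100), ("rep2", SEED + 200)):
        track = synth.simulate_chip_coverage(
            GENOME_LENGTH, truth, background=1.0, fragment_sd=60, seed=rep_seed
        )
        pd.DataFrame({"position": range(len(track)), "coverage": track.values}).to_csv(
            os.path.join(OUT, f"coverage_{rep}.tsv.gz"), sep="\t", index=False
        )
        with open(os.path.join(OUT, f"total_reads_{rep}.txt"), "w") as fh:
            fh.write(str(track.total_reads))
        print(f"{rep}: {track.total_reads} fragments simulated")

    n_aag = sum(1 for s in specs if s.pam == "AAG")
    print(
        f"planted 1 on-target + 60 off-target sites "
        f"({n_aag - 1} off-target AAG, {61 - n_aag} suboptimal-PAM) "
        f"in a {GENOME_LENGTH // 1000}-kb genome -> {os.path.abspath(OUT)}"
    )


if __name__ == "__main__":
    main()
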