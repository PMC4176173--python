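#!/usr/bin/env python
"""Synthetic RNA-seq mismatch-rate experiment: 2 genotypes x 2 reverse
transcriptases, paired seeds.

Finding: the pipeline recovers each condition's injected combined
per-base error rate; libraries built with the higher-fidelity RT show
lower mismatch rates, and the mutant genotype (elevated transcription
errors) shows higher rates than the wild type with either enzyme.
"""

from pathlib import Path

from rnapjam import fidelity as fp
from rnapjam import presets
from rnapjam import synthetic_data as sd

OUT = Path("results/fidelity")
OUT.mkdir(parents=True, exist_ok=True)

ref = sd.generate_reference(10_000, gc=0.4, seed=11)
sd.write_fasta(ref, OUT / "reference.fasta")

rows = ["condition\tinjected_pct\tper_base_rate_pct\tper_read_mean\treads_with_mismatch_pct\taligned_reads"]
for name, cfg in presets.FIDELITY_PRESETS.items():
    model = sd.ErrorModel(**cfg, seed=101)
    records, manifest = sd.generate_reads(ref, 4000, model=model)
    reads = [
        fp.Read(r.id, str(r.seq), tuple(r.letter_annotations["phred_quality"]))
        for r in records
    ]
    report, _ = fp.run_pipeline(reads, ref)
    injected = 100 * sd.combined_error_probability(model)
    rows.append(
        f"{name}\t{injected:.4f}\t{report.per_base_rate:.4f}\t"
        f"{report.per_read_mean:.4f}\t{report.reads_with_mismatch_fraction:.2f}\t"
        f"{report.n_aligned_reads}"
    )
    report.to_tsv(OUT / f"report_{name}.tsv")
    print(
        f"{name}: injected {injected:.3f}% -> measured {report.per_base_rate:.3f}% "
        f"({report.n_aligned_reads} aligned reads)"
    )
(OUT / "summary.tsv").write_text("\n".join(rows) + "\n")
print(f"wrote per-condition reports to {OUT}/")
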