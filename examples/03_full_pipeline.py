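"""Full pipeline on files, exactly as the CLI runs it.

Writes a simulated trio to TSV, then runs qc -> means -> de/spe ->
additivity -> ase -> cistrans -> enrichment from those files and prints
the summary. Equivalent shell usage:

    triohet simulate --outdir sim --seed 5 --n-genes 300
    triohet run-all --tpm sim/tpm.tsv --counts sim/counts.tsv \
        --samples sim/samples.tsv --allele-counts sim/allele_counts.tsv \
        --outdir out
"""

import json
import tempfile
from pathlib import Path

from triohet.pipeline import PipelineConfig, run_pipeline
from triohet.simulate import SimConfig, simulate_trio

tmp = Path(tempfile.mkdtemp(prefix="triohet_example_"))
sim = simulate_trio(SimConfig(n_genes=300, n_tissues=2, seed=5))
sim.matrix.to_tsv(tmp / "tpm.tsv", layer="tpm")
sim.matrix.to_tsv(tmp / "counts.tsv", layer="counts")
sim.sheet.to_tsv(tmp / "samples.tsv")
sim.allele_counts.to_csv(tmp / "allele_counts.tsv", sep="\t", index=False)

cfg = PipelineConfig(
    tpm_path=str(tmp / "tpm.tsv"),
    counts_path=str(tmp / "counts.tsv"),
    sample_sheet_path=str(tmp / "samples.tsv"),
    allele_counts_path=str(tmp / "allele_counts.tsv"),
    library_size=sim.library_per_sample,
    outdir=str(tmp / "out"),
)
summary = run_pipeline(cfg)

print("stages:", " -> ".join(summary["stages"]))
print("QC-flagged samples:", summary["qc"]["flagged"] or "none")
print("parental DEGs per tissue:", summary["deg_counts"])
print("SPE events per tissue:", summary["spe_counts"])
for tissue, s in summary["additivity"].items():
    props = s["deg"]["proportions"]
    print(f"{tissue}: {100 * props['additive']:.1f}% of DEGs additive in the hybrid")
if "enrichment" in summary:
    e = summary["enrichment"]
    print(f"regulatory x expression association: chi2={e['chi2']:.1f}, "
          f"df={e['df']}, p={e['p_global']:.3g}")
print("outputs in", cfg.outdir)
print(json.dumps(summary.get("regulatory", {}), indent=2)[:400])
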