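"""Run the whole analysis on a synthetic study with known ground truth.

Generates the default synthetic bundle (2 x 500 kb chromosomes, 60 genes,
half in head-to-head pairs, CpG-island-like bidirectional promoters, three
planted motifs), writes it to disk, and runs every pipeline stage.
"""

import json
import tempfile
from pathlib import Path

from bidipromoter import PipelineConfig, SimulationConfig, generate_bundle, run_pipeline

workdir = Path(tempfile.mkdtemp(prefix="bidipromoter_demo_"))
bundle = generate_bundle(SimulationConfig(seed=1), out_dir=workdir / "inputs")
print(f"synthetic inputs in {workdir / 'inputs'}: "
      f"{len(bundle.manifest['genome']['pairs'])} planted pairs, "
      f"{len(bundle.manifest['genome']['unidirectional'])} planted uni genes")

config = PipelineConfig(
    genes=workdir / "inputs" / "genes.tsv",
    genome=workdir / "inputs" / "genome.fa",
    obo=workdir / "inputs" / "ontology.obo",
    annotations=workdir / "inputs" / "annotations.tsv",
    jaspar=workdir / "inputs" / "motifs.jaspar",
    transfac=workdir / "inputs" / "motifs.transfac",
    out_dir=workdir / "out",
)
report = run_pipeline(config)

print(f"pairs classified: {report['n_pairs']}, "
      f"uni-directional genes: {report['n_unidirectional']}")
for name, summary in report["cpg_summary_plain"].items():
    print(
        f"CpG islands ({name}): "
        f"{100 * summary['bidirectional']['fraction_with_island']:.1f}% of "
        f"bidirectional vs "
        f"{100 * summary['unidirectional']['fraction_with_island']:.1f}% of "
        f"uni-directional promoters"
    )
print("motif categories:", json.dumps(report["tfbs_categories"]))
print("over-represented in both PWM collections:", sorted(report["tfbs_overlap"]))
print(f"all stage outputs under {workdir / 'out'}")
# The classification recovers exactly the planted pairs, the CpG island
# fraction is far higher in bidirectional promoters (as planted), and the
# 5x-planted motif synm_a is the one over-represented in both collections.
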