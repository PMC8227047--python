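#!/usr/bin/env python
"""Generate the demo cohort: 8 subjects x 2 sampling schemes x 2 scales.

Writes the per-subject streamline-count matrices, manifest and planted
ground truth under scratch/demo_data/ (regenerable; the matrices are bulky).
"""

from pathlib import Path

from strucnet.pipeline import PipelineConfig
from strucnet.synth import generate_ensemble

REPO = Path(__file__).resolve().parent.parent
OUT = REPO / "scratch" / "demo_data"


def main() -> None:
    cfg = PipelineConfig.from_yaml(REPO / "configs" / "demo.yaml")
    data = generate_ensemble(cfg.simulate, out_dir=OUT)
    print(f"wrote {len(data.manifest.entries)} connectome matrices to {OUT}")
    for scale, info in data.truth["scales"].items():
        print(
            f"  scale {scale}: base network with {info['base_edges']} edges,"
            f" {len(info['hubs'])} planted hub nodes"
        )
    print("manifest: scratch/demo_data/manifest.json")
    print("planted truth: scratch/demo_data/truth.json")


if __name__ == "__main__":
    main()
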