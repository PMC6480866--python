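"""Simulate the two synthetic allergy-model studies used by the analyses.

Generates a CMA-flavoured study (3 experiments, 5 arms x 6 animals each,
66-feature panel, SCFA block coupled to the clinical axis) and a
PNA-flavoured study (2 experiments, 5 arms x 7 animals, 33-feature panel
sharing a ~20-feature core, SCFA block decoupled), then writes them as
per-experiment CSVs plus metadata and variable specs under
results/studies/.
"""

import argparse
from pathlib import Path

from oitnet.synthetic_data import (
    build_ground_truth,
    cma_config,
    pna_config,
    simulate_study,
    write_study,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "studies")
    args = parser.parse_args()

    for flavour, cfg, n_per_arm in (("cma", cma_config(), 6),
                                    ("pna", pna_config(), 7)):
        truth = build_ground_truth(cfg)
        study = simulate_study(truth, n_per_arm=n_per_arm, seed=args.seed)
        outdir = args.out / flavour
        write_study(study, outdir)
        print(
            f"{truth.name}: {len(study.experiments)} experiments, "
            f"{study.n_samples()} animals, {len(truth.features)} features "
            f"-> {outdir}"
        )


if __name__ == "__main__":
    main()
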