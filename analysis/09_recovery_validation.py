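"""09 - End-to-end recovery validation.

Runs the full pipeline (simulate -> landscape -> discovery ->
clustering -> annotation -> SSRs -> dating -> runs tests) on the sparse
survey configuration from 03 and scores every stage against the planted
ground truth: clone-class confusion, family recall, base-level
precision/recall of the annotation, SSR recall/precision, and family
age errors.

Run from the repository root: python analysis/09_recovery_validation.py
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

from repeatscape import pipeline

RESULTS = Path("results")
SCRATCH = Path("scratch/runs/sparse")

# the sparse configuration is defined once, in 03
_spec = importlib.util.spec_from_file_location(
    "discovery_driver", Path(__file__).parent / "03_repeat_discovery.py"
)
discovery_driver = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(discovery_driver)


def main() -> None:
    config = pipeline.PipelineConfig(simulation=discovery_driver.sparse_config())
    result = pipeline.run_full(config, SCRATCH)
    report = pipeline.recovery_report(result, config)

    confusion = report.pop("clone_class_confusion")
    rows = [{"metric": k, "value": v} for k, v in report.items()]
    for planted in confusion.index:
        for called in confusion.columns:
            rows.append(
                {
                    "metric": f"clones_planted_{planted}_called_{called}",
                    "value": int(confusion.loc[planted, called]),
                }
            )
    table = pd.DataFrame(rows)
    table["value"] = table["value"].map(
        lambda v: round(v, 4) if isinstance(v, float) else v
    )
    table.to_csv(RESULTS / "09_recovery.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
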