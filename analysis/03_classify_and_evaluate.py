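#!/usr/bin/env python
"""Lodged-rice mapping under the three feature cases: run the full pipeline
(simulate → features → screen → MLC crop mask → Random Forest → confusion
matrix) on one synthetic scene and report PA/UA/OA/Kappa per case.

Finding (seed 0): the optical-only case outperforms the SAR-only case by a
wide margin on these scenes, and the fused SAR+optical case sits at or near
the optical-only accuracy — the SAR channel is speckle-limited at ENL 4
while nine informative optical bands combine to a very strong classifier.

Writes results/case_accuracy.csv and results/case_summary.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lodgemap.pipeline import RunConfig, run_all

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    res = run_all(RunConfig(seed=args.seed, compute_maps=False))

    rows = []
    for case, r in res.cases.items():
        disp = r.report.rounded()
        rows.append(
            {
                "case": case,
                "n_features": len(r.features),
                "features": " | ".join(r.features),
                "PA_lodged_%": disp["PA"][0],
                "PA_healthy_%": disp["PA"][1],
                "UA_lodged_%": disp["UA"][0],
                "UA_healthy_%": disp["UA"][1],
                "OA_%": disp["OA"],
                "Kappa": disp["Kappa"],
            }
        )
        print(f"\n=== case {case} ({len(r.features)} features) ===")
        print(r.report.to_frame())

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "case_accuracy.csv", index=False)
    (OUT / "case_summary.json").write_text(json.dumps(res.summary(), indent=1, default=str))
    print(f"\nwrote {OUT / 'case_accuracy.csv'} and {OUT / 'case_summary.json'}")


if __name__ == "__main__":
    main()
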