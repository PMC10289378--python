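"""Sucrose-gradient qPCR: Ct values to percent-of-total RNA per fraction.

Converts the simulated 12-fraction Ct table to the percentage distribution
(input Ct as ΔCt reference), verifies recovery of the simulated truth, and
demonstrates the ΔΔCt relative-expression readout.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from l1quant.bench_quant import ddct_relative_expression
from l1quant.io_formats import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main(seed: int = 1) -> None:
    files = run_pipeline(
        RunConfig(seed=seed), "gradient", OUT, ct_path=DATA / "gradient_ct.tsv"
    )
    out = pd.read_csv(files[0], sep="\t", comment="#")
    err = np.abs(out["percent"] - out["true_percent"]).max()
    peak = out.loc[out["percent"].idxmax(), "fraction"]
    print(out[["fraction", "ct", "percent"]].round(3).to_string(index=False))
    print(f"peak fraction {peak} (early polysomes), max recovery error {err:.3f} points")

    # ΔΔCt example: target one cycle lower in treatment, reference unchanged
    fold = ddct_relative_expression(19.0, 18.0, 20.0, 18.0)
    print(f"ddCt worked example: one-cycle gain -> fold change {fold:.2f}")
    print(f"wrote {files[0]}")


if __name__ == "__main__":
    main()
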