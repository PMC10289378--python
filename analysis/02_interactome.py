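"""Call high-confidence ORF1p interactors from the simulated IP-MS data.

Applies background subtraction, the 300 mM KCl stringency filter and
replicate/experiment intersection, then scores the recovered set against
the simulation truth and reports the RNase dependence classes.
"""

from pathlib import Path

import pandas as pd

from l1quant.io_formats import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main(seed: int = 1) -> None:
    files = run_pipeline(
        RunConfig(seed=seed), "interactome", OUT, psm_path=DATA / "psm_table.tsv"
    )
    res = pd.read_csv(files[0], sep="\t", comment="#")
    truth = pd.read_csv(DATA / "psm_truth.tsv", sep="\t", comment="#")
    called = set(res.loc[res["is_interactor"], "protein_id"]) - {"ORF1p"}
    positives = set(
        truth.loc[
            truth["entity_class"].isin(["true_interactor", "rnase_sensitive"]), "entity_id"
        ]
    )
    tp = len(called & positives)
    print(f"called {len(called)} interactors (+ bait)")
    print(f"precision {tp / len(called):.3f}, recall {tp / len(positives):.3f}")
    print("RNase classes of called set:")
    print(res.loc[res["is_interactor"], "rnase_class"].value_counts().to_string())
    print(f"wrote {files[0]}")


if __name__ == "__main__":
    main()
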