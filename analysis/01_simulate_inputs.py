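"""Generate every synthetic input class with ground truth.

Writes the IP-MS spectral-count table, the co-IP count matrix with its
sample sheet and annotation, transcript coverage, the gradient qPCR table
and their truth tables under results/data/, in exactly the formats the
downstream stages read.  Plate images are rendered on the fly by
06_colony_assay.py (they are large and cheap to regenerate).
"""

from pathlib import Path

from l1quant.io_formats import RunConfig, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 1) -> None:
    files = run_pipeline(RunConfig(seed=seed), "simulate", OUT)
    print(f"simulated all input classes (seed {seed}):")
    for f in files:
        print(f"  {f.relative_to(OUT.parent.parent)}")


if __name__ == "__main__":
    main()
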