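"""Readers/writers, run configuration and the command-line entry points.

File conventions: TSV is tab-separated UTF-8 with ``#`` comment lines;
count matrices may instead be a MatrixMarket coordinate-integer triplet
(``x.mtx`` plus sibling ``x.rows.txt``/``x.cols.txt`` name lists); interval
inputs (bedGraph, BED4) are 0-based half-open.  Transcript coordinates are
assumed strand-resolved upstream, so no strand logic lives here.  All
readers reject malformed input with located errors; writer/reader pairs
round-trip losslessly.

:class:`RunConfig` is a flat key-value text document collecting every
tunable constant of the downstream stages; unknown keys are errors (typo
protection), and defaults equal the published constants where printed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import sys
import warnings
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import __version__

__all__ = [
    "SampleSheet",
    "RunConfig",
    "read_psm_table",
    "write_psm_table",
    "read_sample_sheet",
    "read_count_matrix",
    "write_count_matrix",
    "read_coverage",
    "run_pipeline",
    "main",
]

ROLES = {"TOTAL", "INPUT", "BO", "IP", "IGG"}
NEGATIVE_ROLES = {"BO", "IGG"}


@dataclass
class SampleSheet:
    """Sample roles and replicate structure of a count matrix.

    One row per sample: ``sample_id`` (unique), ``role`` (TOTAL, INPUT, BO,
    IP or IGG), ``replicate`` (positive integer), ``experiment`` and
    free-text ``condition_tags``.  Every IP sample must have a negative
    role (BO or IgG) in the same experiment.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["sample_id", "role", "replicate", "experiment"]
        missing = [c for c in need if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
        bad = set(self.table["role"]) - ROLES
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        if (self.table["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        for exp, grp in self.table.groupby("experiment"):
            roles = set(grp["role"])
            if "IP" in roles and not roles & NEGATIVE_ROLES:
                raise ValueError(
                    f"experiment {exp!r} has IP samples but no negative control (BO/IGG)"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.table.loc[self.table["role"] == role, "sample_id"])


@dataclass
class RunConfig:
    """Every tunable constant of the pipeline, serialisable as key=value text."""

    seed: int = 0
    # interactome
    bait_id: str = "ORF1p"
    neg_high_psm: int = 10
    neg_min_diff: int = 3
    stringency_fold: float = 3.0
    stringency_pooled: bool = True
    rnase_reduction_fold: float = 3.0
    # enrichment
    lfc_threshold: float = 1.0
    padj_threshold: float = 0.05
    # coverage
    n_bins: int = 10
    coverage_mode: str = "depth"  # or "starts": count read 5' ends per bin
    # colony assay
    pixel_size_um: float = 5.0
    min_diameter_um: float = 194.5
    min_circularity: float = 0.45
    max_texture_dm: float = 2.75
    glcm_levels: int = 8
    glcm_distance: int = 1
    watershed_split: bool = False

    def to_file(self, path) -> None:
        lines = [f"# l1quant run configuration (v{__version__})"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _parse_scalar(value.strip())
        return cls(**kwargs)

    def digest(self) -> str:
        blob = ";".join(f"{f.name}={getattr(self, f.name)!r}" for f in dataclasses.fields(self))
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _parse_scalar(text: str):
    if text.startswith(("'", '"')) and text.endswith(("'", '"')):
        return text[1:-1]
    if text in ("True", "False"):
        return text == "True"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


# ---------------------------------------------------------------------------
# PSM tables

_PSM_FILE_COLUMNS = ["protein_id", "mw_kda", "experiment", "condition", "replicate", "psm"]
_SALTS = {"salt_low", "salt_high"}
_RNASES = {"rnase_minus", "rnase_plus"}


def _split_condition(cond: str, where: str) -> tuple[str, str, str]:
    """Parse 'ROLE[:salt][:rnase]' (defaults salt_low, rnase_minus)."""
    parts = cond.split(":")
    role, salt, rnase = parts[0], "salt_low", "rnase_minus"
    if role not in {"IP", "BO", "IGG"}:
        raise ValueError(f"{where}: unknown condition role {role!r}")
    for extra in parts[1:]:
        if extra in _SALTS:
            salt = extra
        elif extra in _RNASES:
            rnase = extra
        else:
            raise ValueError(f"{where}: unknown condition tag {extra!r}")
    return role, salt, rnase


def read_psm_table(path) -> pd.DataFrame:
    """Read a long-format PSM TSV into the internal wide condition layout.

    Expected header: ``protein_id, mw_kda, experiment, condition,
    replicate, psm`` where condition is ``ROLE[:salt][:rnase]``.  Missing
    (protein, sample) pairs are materialised with PSM = 0; negative PSM or
    non-positive MW raise a validation error naming the row.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    missing = [c for c in _PSM_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.psm < 0:
            raise ValueError(f"{path}: row {i}: negative PSM count {row.psm}")
        if not row.mw_kda > 0:
            raise ValueError(f"{path}: row {i}: non-positive molecular weight {row.mw_kda}")
    if df.empty:
        return pd.DataFrame(
            columns=["protein_id", "mw_kda", "experiment", "role", "salt", "rnase",
                     "replicate", "psm"]
        )
    parsed = [
        _split_condition(c, f"{path}: condition {c!r}") for c in df["condition"].astype(str)
    ]
    df[["role", "salt", "rnase"]] = pd.DataFrame(parsed, index=df.index)
    df = df.drop(columns=["condition"])

    # zero-fill: every protein appears in every observed sample slot
    mw = df.groupby("protein_id")["mw_kda"].first()
    slots = df[["experiment", "role", "salt", "rnase", "replicate"]].drop_duplicates()
    grid = pd.merge(
        pd.DataFrame({"protein_id": mw.index}), slots, how="cross"
    )
    out = grid.merge(
        df[["protein_id", "experiment", "role", "salt", "rnase", "replicate", "psm"]],
        how="left",
        on=["protein_id", "experiment", "role", "salt", "rnase", "replicate"],
    )
    out["psm"] = out["psm"].fillna(0).astype(int)
    out.insert(1, "mw_kda", out["protein_id"].map(mw))
    return out


def write_psm_table(table: pd.DataFrame, path) -> None:
    """Write the internal layout back to the on-disk condition encoding."""
    out = table.copy()
    out["condition"] = out["role"] + ":" + out["salt"] + ":" + out["rnase"]
    out[_PSM_FILE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "condition_tags" not in df.columns:
        df["condition_tags"] = ""
    df["condition_tags"] = df["condition_tags"].fillna("")
    return SampleSheet(df)


# ---------------------------------------------------------------------------
# count matrices

def read_count_matrix(path, sheet: SampleSheet, annotation_path=None):
    """Read a feature × sample count matrix (TSV or MatrixMarket triplet).

    Every sample named in the sheet must be a column of the matrix.
    Fractional counts (e.g. from multimapper reassignment upstream) are
    rounded half-to-even with a warning; anything else non-numeric or
    negative is an error.  Returns ``(counts, annotation)`` where the
    annotation frame is None unless ``annotation_path`` is supplied.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        rows = Path(str(path)[: -len(".mtx")] + ".rows.txt").read_text().split()
        cols = Path(str(path)[: -len(".mtx")] + ".cols.txt").read_text().split()
        mat = scipy.io.mmread(path)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        df = pd.DataFrame(dense, index=pd.Index(rows, name="feature_id"), columns=cols)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        df.index.name = "feature_id"
    absent = [s for s in sheet.sample_ids if s not in df.columns]
    if absent:
        raise ValueError(f"{path}: sample sheet column(s) absent from matrix: {absent}")
    df = df[sheet.sample_ids]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric counts")
    if (values < 0).any():
        raise ValueError(f"{path}: negative counts")
    if not np.allclose(values, np.round(values)):
        warnings.warn(
            f"{path}: fractional counts rounded half-to-even at ingest", stacklevel=2
        )
    counts = pd.DataFrame(
        np.round(values).astype(np.int64), index=df.index, columns=df.columns
    )
    annotation = None
    if annotation_path is not None:
        annotation = pd.read_csv(annotation_path, sep="\t", comment="#").set_index("feature_id")
        annotation = annotation.reindex(counts.index)
    return counts, annotation


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# coverage

def read_transcript_lengths(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"transcript_id", "length"} <= set(df.columns):
        raise ValueError(f"{path}: need columns transcript_id, length")
    return dict(zip(df["transcript_id"], df["length"].astype(int)))


def read_coverage(path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-transcript per-base depth from a bedGraph or a BED of reads.

    bedGraph rows (``tx start end depth``, 0-based half-open) must not
    overlap; BED4 rows (``tx start end name``) are read intervals that
    stack additively.  Intervals exceeding the annotated transcript length
    are errors.
    """
    path = Path(path)
    is_bedgraph = path.suffix.lower() in {".bedgraph", ".bg"}
    depth = {tx: np.zeros(int(n)) for tx, n in lengths.items()}
    covered = (
        {tx: np.zeros(int(n), dtype=bool) for tx, n in lengths.items()}
        if is_bedgraph
        else None
    )
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            tx, start, end = parts[0], int(parts[1]), int(parts[2])
            if tx not in depth:
                raise ValueError(f"{path}:{lineno}: unknown transcript {tx!r}")
            if start < 0 or end > len(depth[tx]) or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) outside transcript "
                    f"{tx!r} of length {len(depth[tx])}"
                )
            if is_bedgraph:
                if covered[tx][start:end].any():
                    raise ValueError(f"{path}:{lineno}: overlapping bedGraph interval")
                covered[tx][start:end] = True
                depth[tx][start:end] += float(parts[3])
            else:
                depth[tx][start:end] += 1.0
    return depth


def write_coverage_bedgraph(depth_map: dict[str, np.ndarray], path) -> None:
    """Write per-base depth as run-length-merged bedGraph intervals."""
    with open(path, "w", encoding="utf-8") as fh:
        for tx, vec in depth_map.items():
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vec)]])
            for s, e in zip(starts, ends):
                if vec[s] != 0:
                    fh.write(f"{tx}\t{s}\t{e}\t{vec[s]:g}\n")


# ---------------------------------------------------------------------------
# pipeline driver / CLI

def _provenance(config: RunConfig) -> str:
    return (
        f"# l1quant v{__version__}\n"
        f"# config_hash: {config.digest()}\n"
        f"# seed: {config.seed}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, index=False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig, subcommand: str, out_dir, **inputs) -> list[Path]:
    """Run one pipeline stage and write its result TSVs with provenance.

    Subcommands: ``simulate`` (all synthetic inputs + truth tables),
    ``interactome``, ``enrich``, ``coverage``, ``gradient``, ``colony``.
    Returns the list of files written.  Stage errors propagate; the CLI
    wrapper converts them to a nonzero exit status with the stage name.
    """
    from . import bench_quant, colony_assay, coverage_integrity, ipms_interactome
    from . import rip_enrichment, synthetic_data

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df, name, index=False):
        p = out_dir / name
        _write_tsv(df, p, config, index=index)
        written.append(p)

    if subcommand == "simulate":
        table, truth = synthetic_data.simulate_psm_experiment(seed=config.seed)
        write_psm_table(table, out_dir / "psm_table.tsv")
        written.append(out_dir / "psm_table.tsv")
        emit(truth, "psm_truth.tsv")
        counts, sheet, annotation, ctruth = synthetic_data.simulate_counts(seed=config.seed)
        write_count_matrix(counts, out_dir / "counts.tsv")
        written.append(out_dir / "counts.tsv")
        emit(sheet, "samples.tsv")
        emit(annotation, "annotation.tsv")
        emit(ctruth, "counts_truth.tsv")
        cov, covtruth = synthetic_data.simulate_coverage(seed=config.seed)
        write_coverage_bedgraph(cov, out_dir / "coverage.bedgraph")
        written.append(out_dir / "coverage.bedgraph")
        lengths = pd.DataFrame(
            {"transcript_id": list(cov), "length": [len(v) for v in cov.values()]}
        )
        emit(lengths, "transcript_lengths.tsv")
        emit(covtruth, "coverage_truth.tsv")
        emit(synthetic_data.simulate_gradient(seed=config.seed), "gradient_ct.tsv")
    elif subcommand == "interactome":
        table = read_psm_table(inputs["psm_path"])
        cfg = ipms_interactome.InteractomeConfig(
            bait_id=config.bait_id,
            neg_high_psm=config.neg_high_psm,
            neg_min_diff=config.neg_min_diff,
            stringency_fold=config.stringency_fold,
            stringency_pooled=config.stringency_pooled,
            rnase_reduction_fold=config.rnase_reduction_fold,
        )
        emit(ipms_interactome.build_interactome(table, cfg), "interactome.tsv")
    elif subcommand == "enrich":
        sheet = read_sample_sheet(inputs["sheet_path"])
        counts, annotation = read_count_matrix(
            inputs["counts_path"], sheet, inputs.get("annotation_path")
        )
        sf = rip_enrichment.size_factors(counts)
        ip = sheet.samples_with_role("IP")
        res = pd.DataFrame(index=counts.index)
        for contrast, role in (("bo", "BO"), ("input", "INPUT"), ("total", "TOTAL")):
            ref = sheet.samples_with_role(role)
            t = rip_enrichment.nb_wald_test(
                counts[ip].to_numpy(),
                counts[ref].to_numpy(),
                sf[[sheet.sample_ids.index(s) for s in ip]],
                sf[[sheet.sample_ids.index(s) for s in ref]],
            )
            res[f"lfc_{contrast}"] = t.log2_fold_change
            res[f"pvalue_{contrast}"] = t.p_value
            res[f"padj_{contrast}"] = rip_enrichment.bh_adjust(t.p_value)
        res["category"] = rip_enrichment.classify_bound(
            res, config.lfc_threshold, config.padj_threshold
        )
        emit(res, "enrichment.tsv", index=True)
    elif subcommand == "coverage":
        lengths = read_transcript_lengths(inputs["lengths_path"])
        cov = read_coverage(inputs["coverage_path"], lengths)
        rows = []
        for tx, vec in cov.items():
            bins = coverage_integrity.bin_coverage(vec, config.n_bins)
            rows.append([tx, *bins, coverage_integrity.terminal_integrity_statistic(bins)])
        emit(
            pd.DataFrame(
                rows,
                columns=["transcript_id", *[f"bin_{i}" for i in range(1, 11)], "tis"],
            ),
            "coverage_bins.tsv",
        )
    elif subcommand == "gradient":
        ct = pd.read_csv(inputs["ct_path"], sep="\t", comment="#")
        percents = bench_quant.fraction_percentages(
            ct["ct"].to_numpy(), float(ct["ct_input"].iloc[0])
        )
        emit(ct.assign(percent=percents), "gradient_percent.tsv")
    elif subcommand == "colony":
        assay, audit = colony_assay.quantify_plate_set(
            inputs["conditions"],
            inputs["baseline"],
            config.pixel_size_um,
            colony_assay.GateThresholds(
                config.min_diameter_um, config.min_circularity, config.max_texture_dm
            ),
            colony_assay.GlcmConfig(config.glcm_levels, config.glcm_distance),
        )
        emit(assay, "assay_results.tsv")
        emit(audit, "colony_audit.tsv")
    else:
        raise ValueError(f"unknown subcommand {subcommand!r}")
    return written


@click.group()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None, help="Overrides the config seed.")
@click.option("--out-dir", type=click.Path(), default="l1quant_out", show_default=True)
@click.option("--log-level", default="INFO", show_default=True)
@click.pass_context
def main(ctx, config_path, seed, out_dir, log_level):
    """LINE-1 ORF1p complex quantification pipeline."""
    config = RunConfig.from_file(config_path) if config_path else RunConfig()
    if seed is not None:
        config.seed = seed
    ctx.obj = {"config": config, "out_dir": out_dir}


def _stage(ctx, subcommand, **inputs):
    try:
        files = run_pipeline(ctx.obj["config"], subcommand, ctx.obj["out_dir"], **inputs)
    except Exception as exc:  # pragma: no cover - exercised via CLI tests
        click.echo(f"error in stage {subcommand}: {exc}", err=True)
        sys.exit(1)
    for f in files:
        click.echo(f"wrote {f}")


@main.command()
@click.pass_context
def simulate(ctx):
    """Generate every synthetic input class with ground truth."""
    _stage(ctx, "simulate")


@main.command()
@click.argument("psm_path", type=click.Path(exists=True))
@click.pass_context
def interactome(ctx, psm_path):
    """Call high-confidence interactors from a PSM table."""
    _stage(ctx, "interactome", psm_path=psm_path)


@main.command()
@click.argument("counts_path", type=click.Path(exists=True))
@click.argument("sheet_path", type=click.Path(exists=True))
@click.option("--annotation", "annotation_path", type=click.Path(exists=True), default=None)
@click.pass_context
def enrich(ctx, counts_path, sheet_path, annotation_path):
    """Test IP enrichment and classify bound mRNAs."""
    _stage(
        ctx, "enrich",
        counts_path=counts_path, sheet_path=sheet_path, annotation_path=annotation_path,
    )


@main.command()
@click.argument("coverage_path", type=click.Path(exists=True))
@click.argument("lengths_path", type=click.Path(exists=True))
@click.pass_context
def coverage(ctx, coverage_path, lengths_path):
    """Bin transcript coverage into deciles and score terminal integrity."""
    _stage(ctx, "coverage", coverage_path=coverage_path, lengths_path=lengths_path)


@main.command()
@click.argument("ct_path", type=click.Path(exists=True))
@click.pass_context
def gradient(ctx, ct_path):
    """Convert gradient qPCR Cts to percent-of-total distributions."""
    _stage(ctx, "gradient", ct_path=ct_path)


@main.command()
@click.argument("image_paths", nargs=-1, type=click.Path(exists=True))
@click.option("--pixel-size-um", type=float, default=None)
@click.pass_context
def colony(ctx, image_paths, pixel_size_um):
    """Segment plate images and count gated colonies (audit only)."""
    import tifffile
    from . import colony_assay as ca

    config = ctx.obj["config"]
    if pixel_size_um is not None:
        config.pixel_size_um = pixel_size_um
    out_dir = Path(ctx.obj["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    try:
        for p in image_paths:
            img = tifffile.imread(p) if str(p).lower().endswith((".tif", ".tiff")) else _read_png(p)
            count, audit = ca.count_colonies(img, config.pixel_size_um)
            audit.insert(0, "image", str(p))
            rows.append(audit)
            click.echo(f"{p}: {count} colonies")
        audit = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        _write_tsv(audit, out_dir / "colony_audit.tsv", config)
    except Exception as exc:
        click.echo(f"error in stage colony: {exc}", err=True)
        sys.exit(1)
    click.echo(f"wrote {out_dir / 'colony_audit.tsv'}")


def _read_png(path):
    from PIL import Image

    return np.asarray(Image.open(path).convert("I"))
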