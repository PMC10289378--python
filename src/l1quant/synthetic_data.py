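"""Ground-truth generators for every pipeline input class.

The study's raw data (testis IP-MS spectral counts, ORF1p co-IP RNA-seq,
sucrose-gradient qPCR, stained colony plates) are emulated here so every
stage is testable against a known truth table:

* :func:`simulate_psm_experiment` — Poisson spectral counts over two
  independent IP-MS experiments with bait, negative-control background,
  salt-sensitive and RNase-sensitive interactor subsets.
* :func:`simulate_counts` — negative-binomial RNA-seq counts across
  TOTAL/INPUT/BO/IP roles with a spiked ORF1p-bound fraction.
* :func:`simulate_coverage` — uniform vs 3'-truncated transcript coverage.
* :func:`simulate_gradient` — 12-fraction qPCR Ct values consistent with a
  target percentage distribution plus cycle noise.
* :func:`simulate_plate` — grayscale plate images of textured
  quasi-circular colonies plus sub-threshold, elongated and noisy clutter.

Every generator is a pure function of its parameters and an explicit seed
(numpy ``default_rng``); truth tables always agree with the emitted data.
PSM counts are Poisson rather than negative-binomial: spectral counts are
low-mean, and over-dispersion is left as an extension.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "simulate_psm_experiment",
    "simulate_counts",
    "simulate_coverage",
    "simulate_gradient",
    "simulate_plate",
    "DEFAULT_GRADIENT_PERCENT",
]

# L1 RNA distribution across a 10-50% sucrose gradient, peaking in the
# early polysomal fractions 6-8 (percent of total detected RNA).
DEFAULT_GRADIENT_PERCENT = np.array(
    [2.0, 3.0, 4.0, 6.0, 8.0, 14.0, 16.0, 14.0, 10.0, 9.0, 8.0, 6.0]
)


def simulate_psm_experiment(
    n_proteins: int = 1000,
    n_true: int = 100,
    enrichment: float = 8.0,
    background_rate: float = 2.0,
    replicates: int = 3,
    seed: int = 0,
    *,
    n_salt_sensitive: int = 10,
    n_rnase_sensitive: int = 10,
    salt_drop: float = 8.0,
    rnase_drop: float = 8.0,
    bait_id: str = "ORF1p",
    bait_rate: float = 100.0,
    experiments: tuple[str, ...] = ("E1", "E2"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-experiment IP-MS spectral-count table with truth.

    Every protein has a per-protein background abundance drawn from a
    Gamma distribution with mean ``background_rate``; negative-control
    (beads-only) counts are Poisson at that abundance in all conditions.
    True interactors (and the salt-/RNase-sensitive subsets) are enriched
    ``enrichment``-fold in the IP; salt-sensitive proteins drop
    ``salt_drop``-fold (> 3) under the 300 mM KCl wash, RNase-sensitive
    proteins drop ``rnase_drop``-fold after nuclease digestion.  The bait
    is fixed high (``bait_rate``) in every IP sample.

    Returns ``(psm_table, truth)``: a long-format table with columns
    ``protein_id, mw_kda, experiment, role, salt, rnase, replicate, psm``,
    and a truth table ``entity_id, entity_class, effect_size``.
    """
    n_special = n_true + n_salt_sensitive + n_rnase_sensitive
    if n_special > n_proteins:
        raise ValueError("n_true + sensitive subsets exceed n_proteins")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    rng = np.random.default_rng(seed)

    width = len(str(n_proteins))
    ids = np.array([f"P{i + 1:0{width}d}" for i in range(n_proteins)])
    classes = np.array(["background"] * n_proteins, dtype=object)
    classes[:n_true] = "true_interactor"
    classes[n_true : n_true + n_salt_sensitive] = "salt_sensitive"
    classes[n_true + n_salt_sensitive : n_special] = "rnase_sensitive"

    abundance = rng.gamma(shape=4.0, scale=background_rate / 4.0, size=n_proteins)
    mw = rng.uniform(15.0, 250.0, size=n_proteins)
    enriched = np.isin(classes, ["true_interactor", "salt_sensitive", "rnase_sensitive"])

    ip_rate = np.where(enriched, abundance * enrichment, abundance)
    ip_high_rate = np.where(classes == "salt_sensitive", ip_rate / salt_drop, ip_rate)
    ip_rnase_rate = np.where(classes == "rnase_sensitive", ip_rate / rnase_drop, ip_rate)

    rows = []

    def emit(exp, role, salt, rnase, rep, prot_ids, mws, counts):
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": prot_ids,
                    "mw_kda": mws,
                    "experiment": exp,
                    "role": role,
                    "salt": salt,
                    "rnase": rnase,
                    "replicate": rep,
                    "psm": counts,
                }
            )
        )

    for exp in experiments:
        for rep in range(1, replicates + 1):
            emit(exp, "BO", "salt_low", "rnase_minus", rep, ids, mw, rng.poisson(abundance))
            for salt, rnase, rate in (
                ("salt_low", "rnase_minus", ip_rate),
                ("salt_high", "rnase_minus", ip_high_rate),
                ("salt_low", "rnase_plus", ip_rnase_rate),
            ):
                emit(exp, "IP", salt, rnase, rep, ids, mw, rng.poisson(rate))
                # bait: constant high recovery in the IP, trace in BO
                emit(exp, "IP", salt, rnase, rep, [bait_id], [40.0],
                     [1 + rng.poisson(bait_rate)])
            emit(exp, "BO", "salt_low", "rnase_minus", rep, [bait_id], [40.0],
                 [rng.poisson(background_rate)])

    table = pd.concat(rows, ignore_index=True)
    table = (
        table.groupby(
            ["protein_id", "mw_kda", "experiment", "role", "salt", "rnase", "replicate"],
            as_index=False, sort=False,
        )["psm"].sum()
    )
    effect = np.where(enriched, enrichment, 1.0)
    effect = np.where(classes == "salt_sensitive", salt_drop, effect)
    truth = pd.DataFrame({"entity_id": ids, "entity_class": classes, "effect_size": effect})
    return table.reset_index(drop=True), truth


def simulate_counts(
    n_features: int = 2000,
    n_bound: int = 200,
    fold: float = 4.0,
    dispersion: float = 0.1,
    lib_sizes: np.ndarray | None = None,
    seed: int = 0,
    *,
    replicates: int = 3,
    baseline_log_mean: float = math.log(100.0),
    baseline_log_sd: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a co-IP count matrix (TOTAL/INPUT/BO/IP in triplicate).

    Per-feature baselines are log-normal, so expression spans orders of
    magnitude.  Counts are NB with ``variance = mu + dispersion * mu^2``
    (``dispersion = 0`` degenerates to Poisson); bound features get a
    ``fold`` multiplier in IP samples only.

    Returns ``(counts, sample_sheet, annotation, truth)``.
    """
    if not 0 <= n_bound <= n_features:
        raise ValueError("need 0 <= n_bound <= n_features")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if fold < 1:
        raise ValueError("bound fold must be >= 1")
    rng = np.random.default_rng(seed)
    roles = ["TOTAL", "INPUT", "BO", "IP"]
    samples = [f"{r}_{i + 1}" for r in roles for i in range(replicates)]
    if lib_sizes is None:
        lib_sizes = np.ones(len(samples))
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if lib_sizes.shape != (len(samples),) or (lib_sizes <= 0).any():
        raise ValueError(f"lib_sizes must be {len(samples)} positive reals")

    width = len(str(n_features))
    ids = pd.Index([f"g{i + 1:0{width}d}" for i in range(n_features)], name="feature_id")
    bound = np.zeros(n_features, dtype=bool)
    bound[:n_bound] = fold > 1
    baseline = rng.lognormal(baseline_log_mean, baseline_log_sd, size=n_features)

    mu = np.empty((n_features, len(samples)))
    for j, s in enumerate(samples):
        role = s.rsplit("_", 1)[0]
        mult = np.where(bound & (role == "IP"), fold, 1.0)
        mu[:, j] = baseline * mult * lib_sizes[j]
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(counts, index=ids, columns=samples)

    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "role": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
            "experiment": "RIP",
            "condition_tags": "",
        }
    )
    annotation = pd.DataFrame(
        {
            "feature_id": ids,
            "feature_class": "gene",
            "subfamily": "",
            "max_transcript_length": np.round(rng.lognormal(math.log(2000.0), 0.6, n_features)).astype(int),
        }
    )
    truth = pd.DataFrame(
        {
            "entity_id": ids,
            "entity_class": np.where(bound, "bound_mrna", "unbound_mrna"),
            "effect_size": np.where(bound, fold, 1.0),
        }
    )
    return counts, sheet, annotation, truth


def simulate_coverage(
    n_tx: int = 50,
    depth: int = 100_000,
    truncation: float = 0.0,
    seed: int = 0,
    *,
    frac_degraded: float = 0.5,
    tx_length: int = 2000,
    read_length: int = 1,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-transcript per-base coverage from uniform read starts.

    Intact transcripts receive ``depth`` read starts uniform over the full
    length; when ``truncation > 0`` a ``frac_degraded`` subset loses its 3'
    terminal ``truncation`` fraction (no starts land there).  The default
    ``read_length`` of 1 makes per-base depth an exact multinomial over
    positions; longer reads are extended from the start and clipped at the
    intact 3' boundary.
    """
    if not 0 <= truncation < 1:
        raise ValueError("truncation must be in [0, 1)")
    if n_tx < 1 or depth < 1:
        raise ValueError("need at least one transcript and one read")
    rng = np.random.default_rng(seed)
    n_degraded = int(round(frac_degraded * n_tx)) if truncation > 0 else 0
    coverage: dict[str, np.ndarray] = {}
    records = []
    for i in range(n_tx):
        degraded = i < n_degraded
        tx = f"tx{i + 1:04d}"
        eff_len = tx_length - int(math.floor(truncation * tx_length)) if degraded else tx_length
        starts = rng.integers(0, eff_len, size=depth)
        depth_vec = np.zeros(tx_length)
        if read_length == 1:
            np.add.at(depth_vec, starts, 1)
        else:
            for s in starts:
                depth_vec[s : min(s + read_length, eff_len)] += 1
        coverage[tx] = depth_vec
        records.append(
            {
                "entity_id": tx,
                "entity_class": "degraded_tx" if degraded else "intact_tx",
                "effect_size": truncation if degraded else 1.0,
            }
        )
    return coverage, pd.DataFrame(records)


def simulate_gradient(
    true_percent: np.ndarray | None = None,
    ct_input: float = 20.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    *,
    total_quantity: float = 1.0,
) -> pd.DataFrame:
    """Simulate a 12-fraction gradient qPCR Ct table.

    Each detected fraction's Ct is
    ``ct_input - log2(percent/100 * total_quantity) + Normal(0, noise_sd)``;
    fractions with a true percentage of 0 are emitted as non-detected
    (``NaN``), never as Ct = 0.  Returns a table with columns ``fraction``,
    ``ct``, ``ct_input``, ``true_percent``.
    """
    p = DEFAULT_GRADIENT_PERCENT.copy() if true_percent is None else np.asarray(true_percent, float)
    if p.shape != (12,) or (p < 0).any():
        raise ValueError("true_percent must be 12 non-negative values")
    if not math.isclose(p.sum(), 100.0, abs_tol=1e-6):
        raise ValueError(f"true_percent must sum to 100, got {p.sum()}")
    rng = np.random.default_rng(seed)
    ct = np.full(12, np.nan)
    det = p > 0
    ct[det] = ct_input - np.log2(p[det] / 100.0 * total_quantity) + rng.normal(0, noise_sd, det.sum())
    return pd.DataFrame(
        {"fraction": np.arange(1, 13), "ct": ct, "ct_input": ct_input, "true_percent": p}
    )


# ---------------------------------------------------------------------------
# plate images


def _radial_blob_mask(r0_px: float, rng: np.random.Generator, max_noise: float = 0.12):
    """Boolean mask of a quasi-circular blob with bounded radial noise."""
    n_harm = 4
    amps = rng.uniform(0, 1, n_harm)
    amps *= max_noise / max(amps.sum(), 1e-9) * rng.uniform(0.3, 1.0)
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    half = int(math.ceil(r0_px * (1 + max_noise))) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    theta = np.arctan2(yy, xx)
    rho = np.hypot(yy, xx)
    r_theta = r0_px * (
        1 + sum(a * np.cos((k + 2) * theta + ph) for k, (a, ph) in enumerate(zip(amps, phases)))
    )
    return rho <= r_theta


def _smooth_texture(shape, rng, base: float, amplitude: float, sigma: float = 2.0):
    noise = ndimage.gaussian_filter(rng.normal(0, 1, shape), sigma)
    sd = noise.std() or 1.0
    return base + amplitude * noise / sd


def _rotated_rect_mask(length_px: float, width_px: float, angle: float):
    half = int(math.ceil(math.hypot(length_px, width_px) / 2)) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    u = xx * math.cos(angle) + yy * math.sin(angle)
    v = -xx * math.sin(angle) + yy * math.cos(angle)
    return (np.abs(u) <= length_px / 2) & (np.abs(v) <= width_px / 2)


def simulate_plate(
    n_colonies: int = 50,
    diameter_range: tuple[float, float] = (250.0, 550.0),
    n_clutter: int = 200,
    pixel_size: float = 5.0,
    seed: int = 0,
    *,
    image_size: int | None = None,
    background_level: int = 10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a stained-colony plate image with ground truth.

    Colonies are quasi-circular blobs (radial boundary noise < 15% of the
    radius) with smooth interior staining.  Clutter comes in three kinds,
    each violating exactly one gate: ``speck`` (diameter below the 194.5 µm
    minimum), ``smear`` (elongated, circularity < 0.45) and ``noisy_patch``
    (colony-sized disk with salt-and-pepper staining that fails the
    texture gate).  The background is a constant low gray level so a blank
    plate segments to zero regions.

    Returns ``(image, truth)`` where ``image`` is uint8 grayscale and
    ``truth`` lists ``entity_id, entity_class, clutter_kind, x_px, y_px,
    diameter_um, effect_size``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive (µm per pixel)")
    lo, hi = diameter_range
    if not 0 < lo <= hi:
        raise ValueError("invalid diameter_range")
    rng = np.random.default_rng(seed)

    objects = []  # (kind, mask, intensity_patch, diameter_um)
    for i in range(n_colonies):
        d_um = rng.uniform(lo, hi)
        mask = _radial_blob_mask(d_um / 2 / pixel_size, rng)
        tex = _smooth_texture(mask.shape, rng, base=rng.uniform(160, 210), amplitude=8.0)
        objects.append(("colony", None, mask, tex, d_um))
    kinds = ["speck", "smear", "noisy_patch"]
    for i in range(n_clutter):
        kind = kinds[i % 3]
        if kind == "speck":
            d_um = rng.uniform(30.0, 120.0)
            mask = _radial_blob_mask(d_um / 2 / pixel_size, rng)
            tex = _smooth_texture(mask.shape, rng, base=rng.uniform(160, 210), amplitude=8.0)
        elif kind == "smear":
            length_um = rng.uniform(500.0, 700.0)
            aspect = rng.uniform(6.0, 9.0)
            width_um = length_um / aspect
            mask = _rotated_rect_mask(
                length_um / pixel_size, width_um / pixel_size, rng.uniform(0, np.pi)
            )
            tex = _smooth_texture(mask.shape, rng, base=rng.uniform(160, 210), amplitude=8.0)
            d_um = 2 * math.sqrt(mask.sum() / math.pi) * pixel_size
        else:  # noisy_patch: passes size and shape, fails texture
            d_um = rng.uniform(250.0, 500.0)
            mask = _radial_blob_mask(d_um / 2 / pixel_size, rng, max_noise=0.05)
            tex = rng.uniform(90, 255, mask.shape)
        objects.append(("clutter", kind, mask, tex, d_um))

    # auto image size: generous packing head-room, min 512 px
    if image_size is None:
        total_area = sum(m.sum() for _, _, m, _, _ in objects)
        image_size = max(512, int(math.ceil(math.sqrt(total_area * 10.0))))
    img = np.full((image_size, image_size), background_level, dtype=float)

    occupied = np.zeros_like(img, dtype=bool)
    records = []
    margin = 3
    struct = np.ones((2 * margin + 1, 2 * margin + 1), dtype=bool)
    # place big objects first: rejection sampling then succeeds for the
    # many small ones even on crowded plates
    order = sorted(range(len(objects)), key=lambda i: -int(objects[i][2].sum()))
    for idx in order:
        cls, kind, mask, tex, d_um = objects[idx]
        h, w = mask.shape
        placed = False
        for _attempt in range(1000):
            y = int(rng.integers(margin, image_size - h - margin))
            x = int(rng.integers(margin, image_size - w - margin))
            pad = occupied[max(0, y - margin):y + h + margin, max(0, x - margin):x + w + margin]
            if not pad.any():
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place all objects without overlap; increase image_size"
            )
        img[y:y + h, x:x + w][mask] = tex[mask]
        occupied[y:y + h, x:x + w] |= ndimage.binary_dilation(mask, structure=struct)
        records.append(
            {
                "entity_id": f"obj{idx + 1:04d}",
                "_order": idx,
                "entity_class": cls,
                "clutter_kind": kind or "",
                "x_px": x + w / 2,
                "y_px": y + h / 2,
                "diameter_um": d_um,
                "effect_size": d_um,
            }
        )
    truth = (
        pd.DataFrame(records).sort_values("_order").drop(columns="_order").reset_index(drop=True)
        if records
        else pd.DataFrame(records)
    )
    return np.clip(img, 0, 255).astype(np.uint8), truth


def evaluate_colony_calls(
    audit: pd.DataFrame, truth: pd.DataFrame, max_dist_px: float = 30.0
) -> dict[str, float]:
    """Precision/recall of gated colony calls against plate ground truth.

    A called region (``is_colony`` row of the audit table) is a true
    positive when its centroid lies within ``max_dist_px`` of a true colony
    center; each true colony can be matched at most once.
    """
    from scipy.spatial import cKDTree

    tc = truth[truth["entity_class"] == "colony"]
    called = audit[audit["is_colony"]] if "is_colony" in audit else audit.iloc[0:0]
    if len(tc) == 0:
        return {"precision": 1.0 if len(called) == 0 else 0.0, "recall": 1.0,
                "n_called": float(len(called)), "n_true": 0.0}
    if len(called) == 0:
        return {"precision": 1.0, "recall": 0.0, "n_called": 0.0, "n_true": float(len(tc))}
    tree = cKDTree(tc[["y_px", "x_px"]].to_numpy())
    d, idx = tree.query(called[["centroid_y", "centroid_x"]].to_numpy())
    matched = set(idx[d <= max_dist_px])
    tp_calls = int((d <= max_dist_px).sum())
    return {
        "precision": tp_calls / len(called),
        "recall": len(matched) / len(tc),
        "n_called": float(len(called)),
        "n_true": float(len(tc)),
    }
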