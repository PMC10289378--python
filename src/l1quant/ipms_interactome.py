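"""High-confidence interactor calling from IP-MS spectral counts.

Input is a long-format PSM (peptide-spectrum match) table: one row per
(protein, experiment, condition, replicate) with the spectral count as a
semi-quantitative abundance proxy.  Conditions combine a role (``IP`` or a
negative control, ``BO`` beads-only / ``IGG`` isotype), a wash stringency
(``salt_low`` 100 mM / ``salt_high`` 300 mM KCl) and a nuclease treatment
(``rnase_minus`` / ``rnase_plus``).

The pipeline applies, in order:

1. **Background subtraction** per replicate: a protein is excluded when its
   negative-control count is at least its IP count, or when the negative
   control shows ≥ 10 PSMs and the IP exceeds it by fewer than 3.
2. **Stringency filter** on counts pooled across replicates: proteins that
   drop more than 3-fold, or are lost entirely, at the high-salt wash are
   excluded.
3. **Replicate/experiment intersection**: only proteins surviving in every
   replicate of every experiment are retained.

Survivors are annotated with a bait-normalised abundance,
``(PSM/MW) / (PSM_bait/MW_bait)`` (molecular weight in kDa), and an RNase
dependence class comparing abundance with and without nuclease digestion —
RNase-resistant co-precipitation implies a protein-protein contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "InteractomeConfig",
    "background_filter",
    "stringency_filter",
    "intersect_replicates",
    "normalized_abundance",
    "rnase_dependence",
    "build_interactome",
]

PSM_COLUMNS = ["protein_id", "mw_kda", "experiment", "role", "salt", "rnase", "replicate", "psm"]


@dataclass
class InteractomeConfig:
    """Tunable constants of the interactor pipeline.

    ``neg_high_psm`` / ``neg_min_diff`` parameterise the high-background
    exclusion (defaults 10 and 3); ``stringency_fold`` the salt filter
    (default 3); ``rnase_reduction_fold`` the threshold separating
    "reduced" from "resistant" (default 3 — a stand-in, as no figure prints
    one).  ``stringency_pooled`` selects pooled-vs-per-replicate counts for
    the salt comparison.
    """

    bait_id: str = "ORF1p"
    neg_high_psm: int = 10
    neg_min_diff: int = 3
    stringency_fold: float = 3.0
    stringency_pooled: bool = True
    rnase_reduction_fold: float = 3.0


def background_filter(
    ip_psm: int, neg_psm: int, *, neg_high_psm: int = 10, neg_min_diff: int = 3
) -> tuple[bool, str | None]:
    """Background-subtraction rule for one protein in one replicate.

    Returns ``(keep, rule_id)`` where ``rule_id`` names the exclusion rule
    that fired (``None`` when kept).  Exclusion fires when the negative
    control matches or exceeds the IP (``neg>=ip``), or when the negative
    control is high (PSM ≥ 10) and the IP margin is below 3
    (``high-background, diff<3``).  The margin comparison is strict: a
    difference of exactly 3 is kept.
    """
    if ip_psm < 0 or neg_psm < 0:
        raise ValueError("PSM counts must be non-negative")
    if neg_psm >= ip_psm:
        return False, "neg>=ip"
    if neg_psm >= neg_high_psm and (ip_psm - neg_psm) < neg_min_diff:
        return False, "high-background, diff<3"
    return True, None


def stringency_filter(
    psm_low_salt: int, psm_high_salt: int, *, fold: float = 3.0
) -> bool:
    """Keep/exclude under the high-salt (300 mM KCl) wash comparison.

    Excluded when the protein is completely lost at high salt (low > 0,
    high = 0) or decreases strictly more than ``fold`` times.  A protein
    absent in both washes (0/0) is kept: no evidence of loss.
    """
    if psm_low_salt < 0 or psm_high_salt < 0:
        raise ValueError("PSM counts must be non-negative")
    if psm_high_salt == 0:
        return psm_low_salt == 0
    return psm_low_salt / psm_high_salt <= fold


def intersect_replicates(
    survivors_by_experiment: Mapping[str, Iterable[set]],
) -> set:
    """Proteins common to every replicate of every experiment.

    Within each experiment only proteins present in all replicate survivor
    sets are retained; the high-confidence set is the intersection across
    experiments.
    """
    if not survivors_by_experiment:
        raise ValueError("no experiments supplied")
    final: set | None = None
    for experiment, replicate_sets in survivors_by_experiment.items():
        replicate_sets = [set(s) for s in replicate_sets]
        if not replicate_sets:
            raise ValueError(f"experiment {experiment!r} has no replicates")
        common = set.intersection(*replicate_sets)
        final = common if final is None else final & common
    assert final is not None
    return final


def normalized_abundance(
    psm: int, mw_kda: float, bait_psm: int, bait_mw_kda: float
) -> float:
    """PSM/MW ratio normalised to the bait's ratio (bait itself → 1.0)."""
    if mw_kda <= 0 or bait_mw_kda <= 0:
        raise ValueError("molecular weights must be positive")
    if bait_psm <= 0:
        raise ValueError("bait not recovered (bait PSM must be positive)")
    return (psm / mw_kda) / (bait_psm / bait_mw_kda)


def rnase_dependence(
    abund_minus: float, abund_plus: float, reduction_threshold: float = 3.0
) -> str:
    """Classify RNase dependence: ``resistant``, ``reduced`` or ``lost``.

    ``lost`` — co-precipitation abolished by nuclease digestion (plus = 0
    while minus > 0); ``reduced`` — drops more than ``reduction_threshold``
    fold; otherwise ``resistant`` (including the no-evidence 0/0 case).
    """
    if abund_minus < 0 or abund_plus < 0:
        raise ValueError("abundances must be non-negative")
    if abund_plus == 0:
        return "lost" if abund_minus > 0 else "resistant"
    return "reduced" if abund_minus / abund_plus > reduction_threshold else "resistant"


def _validate_psm_table(table: pd.DataFrame) -> None:
    missing = [c for c in PSM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"PSM table missing columns: {missing}")
    dup = table.duplicated(subset=["protein_id", "experiment", "role", "salt", "rnase", "replicate"])
    if dup.any():
        raise ValueError(
            f"duplicate (protein, experiment, condition, replicate) rows: {int(dup.sum())}"
        )


def _pivot(table: pd.DataFrame, role: str, salt: str, rnase: str) -> pd.DataFrame:
    """Protein × replicate PSM matrix for one (role, salt, rnase) slice, zero-filled."""
    sel = table[(table["role"] == role) & (table["salt"] == salt) & (table["rnase"] == rnase)]
    return sel.pivot_table(
        index="protein_id", columns="replicate", values="psm", aggfunc="sum", fill_value=0
    )


def build_interactome(
    psm_table: pd.DataFrame, config: InteractomeConfig | None = None
) -> pd.DataFrame:
    """Run the full interactor pipeline on a long-format PSM table.

    Returns one record per protein with per-rule survival flags, the final
    ``is_interactor`` verdict, bait-normalised abundance per experiment
    (and their mean), and the RNase dependence class where nuclease-treated
    data exist.  Records are ordered by descending mean abundance, ties
    broken by protein id.

    The negative control for an experiment is beads-only (BO) when present,
    otherwise isotype IgG; when both exist the per-replicate maximum of the
    two is used (conservative).
    """
    config = config or InteractomeConfig()
    _validate_psm_table(psm_table)
    experiments = sorted(psm_table["experiment"].unique())
    if not experiments:
        raise ValueError("PSM table contains no experiments")
    proteins = pd.Index(sorted(psm_table["protein_id"].unique()), name="protein_id")
    mw = psm_table.groupby("protein_id")["mw_kda"].first()
    if (mw <= 0).any():
        raise ValueError("molecular weights must be positive")
    if config.bait_id not in proteins:
        raise ValueError(f"bait {config.bait_id!r} absent from PSM table")

    passed_background = pd.Series(True, index=proteins)
    passed_stringency = pd.Series(True, index=proteins)
    abundance: dict[str, pd.Series] = {}
    abund_minus_all, abund_plus_all = [], []
    has_rnase_plus = False

    for exp in experiments:
        sub = psm_table[psm_table["experiment"] == exp]
        ip = _pivot(sub, "IP", "salt_low", "rnase_minus").reindex(proteins, fill_value=0)
        if ip.loc[config.bait_id].le(0).any():
            raise ValueError(f"bait {config.bait_id!r} not detected in every IP sample of {exp!r}")
        roles_present = set(sub["role"].unique())
        neg_frames = []
        for neg_role in ("BO", "IGG"):
            if neg_role in roles_present:
                neg_frames.append(
                    _pivot(sub, neg_role, "salt_low", "rnase_minus")
                    .reindex(index=proteins, columns=ip.columns, fill_value=0)
                )
        if not neg_frames:
            raise ValueError(f"experiment {exp!r} has no negative-control (BO/IGG) samples")
        neg = neg_frames[0] if len(neg_frames) == 1 else np.maximum(neg_frames[0], neg_frames[1])

        # background rule, vectorised over the protein x replicate matrices
        excl = (neg.values >= ip.values) | (
            (neg.values >= config.neg_high_psm)
            & ((ip.values - neg.values) < config.neg_min_diff)
        )
        passed_background &= pd.Series(~excl.any(axis=1), index=proteins)

        high = _pivot(sub, "IP", "salt_high", "rnase_minus")
        if not high.empty:
            high = high.reindex(proteins, fill_value=0)
            if config.stringency_pooled:
                low_c = ip.sum(axis=1).to_numpy()
                high_c = high.sum(axis=1).to_numpy()
                keep = _stringency_vec(low_c, high_c, config.stringency_fold)
            else:
                cols = ip.columns.intersection(high.columns)
                keep = np.ones(len(proteins), dtype=bool)
                for c in cols:
                    keep &= _stringency_vec(
                        ip[c].to_numpy(), high[c].to_numpy(), config.stringency_fold
                    )
            passed_stringency &= pd.Series(keep, index=proteins)

        pooled = ip.sum(axis=1)
        bait_psm = int(pooled.loc[config.bait_id])
        bait_mw = float(mw.loc[config.bait_id])
        abundance[exp] = (pooled / mw.reindex(proteins)) / (bait_psm / bait_mw)

        plus = _pivot(sub, "IP", "salt_low", "rnase_plus")
        if not plus.empty:
            has_rnase_plus = True
            plus = plus.reindex(proteins, fill_value=0).sum(axis=1)
            bait_plus = int(plus.loc[config.bait_id])
            abund_minus_all.append(abundance[exp])
            abund_plus_all.append(
                (plus / mw.reindex(proteins)) / (bait_plus / bait_mw)
                if bait_plus > 0
                else pd.Series(0.0, index=proteins)
            )

    result = pd.DataFrame(index=proteins)
    result["mw_kda"] = mw.reindex(proteins)
    result["passed_background"] = passed_background
    result["passed_stringency"] = passed_stringency
    result["is_interactor"] = passed_background & passed_stringency
    for exp in experiments:
        result[f"abundance_{exp}"] = abundance[exp]
    result["normalized_abundance"] = pd.concat(abundance, axis=1).mean(axis=1)
    if has_rnase_plus:
        am = pd.concat(abund_minus_all, axis=1).mean(axis=1)
        ap = pd.concat(abund_plus_all, axis=1).mean(axis=1)
        result["rnase_class"] = [
            rnase_dependence(am[p], ap[p], config.rnase_reduction_fold) for p in proteins
        ]
    else:
        result["rnase_class"] = pd.NA
    result = result.reset_index().sort_values(
        ["normalized_abundance", "protein_id"], ascending=[False, True], kind="mergesort"
    )
    return result.reset_index(drop=True)


def _stringency_vec(low: np.ndarray, high: np.ndarray, fold: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(high > 0, low / np.maximum(high, 1), np.inf)
    lost = (high == 0) & (low > 0)
    both_zero = (high == 0) & (low == 0)
    return both_zero | (~lost & (ratio <= fold))
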