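"""Fixed-effect inverse-variance meta-analysis of two-study effect tables.

Correlations are pooled on the Fisher-z scale (z = atanh(r), SE = 1/sqrt(n-3))
and reported on that scale, with an optional back-transformed column; means
are pooled directly from per-study (mean, SE) pairs. The reference
distribution for CIs and the pooled z statistic is the standard normal
(CI half-width 1.96 * SE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EffectKind = Literal["mean", "fisher_z"]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class MetaError(ValueError):
    pass


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform of a correlation: atanh(r)."""
    if not -1.0 < r < 1.0:
        raise MetaError(f"|r| must be < 1, got {r}")
    return math.atanh(r)


def inv_fisher_z(z: float) -> float:
    """Back-transform a Fisher z to a correlation: tanh(z)."""
    return math.tanh(z)


def se_fisher(n: int) -> float:
    """Standard error of a Fisher z from a sample of size n: 1/sqrt(n-3)."""
    if n < 4:
        raise MetaError(f"Fisher-z SE requires n >= 4, got {n}")
    return 1.0 / math.sqrt(n - 3)


@dataclass(frozen=True)
class EffectSize:
    """One study's effect estimate on a common scale."""

    study_id: str
    kind: EffectKind
    estimate: float
    se: float
    n: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("mean", "fisher_z"):
            raise MetaError(f"kind must be 'mean' or 'fisher_z', got {self.kind!r}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise MetaError(f"se must be finite and > 0, got {self.se}")

    @classmethod
    def from_correlation(cls, study_id: str, r: float, n: int, label: str = "") -> "EffectSize":
        return cls(
            study_id=study_id, kind="fisher_z",
            estimate=fisher_z(r), se=se_fisher(n), n=n, label=label,
        )


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effect estimate with normal-theory inference."""

    pooled_estimate: float
    pooled_se: float
    ci_low: float
    ci_high: float
    z_stat: float
    p: float
    kind: EffectKind = "mean"
    label: str = ""


def pool_fixed(effects: Sequence[EffectSize]) -> MetaResult:
    """Inverse-variance fixed-effect pooling of same-kind effects.

    weights w_i = 1/se_i^2; pooled = sum(w e)/sum(w); pooled SE =
    1/sqrt(sum(w)); two-sided p against pooled effect 0.
    """
    if not effects:
        raise MetaError("pool_fixed requires at least one effect")
    kinds = {e.kind for e in effects}
    if len(kinds) > 1:
        raise MetaError(f"cannot pool mixed effect kinds: {sorted(kinds)}")
    est = np.array([e.estimate for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    pooled = float((w * est).sum() / w.sum())
    pooled_se = float(1.0 / math.sqrt(w.sum()))
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    labels = {e.label for e in effects}
    return MetaResult(
        pooled_estimate=pooled,
        pooled_se=pooled_se,
        ci_low=pooled - _Z95 * pooled_se,
        ci_high=pooled + _Z95 * pooled_se,
        z_stat=float(z),
        p=p,
        kind=effects[0].kind,
        label=labels.pop() if len(labels) == 1 else "",
    )


def effects_from_study_frame(study_id: str, frame: pd.DataFrame) -> list[EffectSize]:
    """Build effects from one study's table.

    Two layouts are accepted:

    * correlation rows: columns ``label`` (or ``pair``), ``r``, ``n``;
    * mean rows: columns ``label``, ``mean`` (or ``estimate``), ``se``.

    A single frame may mix row layouts; each row is typed by which fields
    are present (non-null).
    """
    cols = {c.lower(): c for c in frame.columns}
    label_col = cols.get("label") or cols.get("pair")
    if label_col is None:
        raise MetaError("study table needs a 'label' (or 'pair') column")
    effects: list[EffectSize] = []
    for _, row in frame.iterrows():
        label = str(row[label_col])
        r_val = row[cols["r"]] if "r" in cols else None
        if r_val is not None and pd.notna(r_val):
            if "n" not in cols or pd.isna(row[cols["n"]]):
                raise MetaError(f"row {label!r}: correlation rows need an 'n' column")
            effects.append(
                EffectSize.from_correlation(study_id, float(r_val), int(row[cols["n"]]), label=label)
            )
            continue
        mean_col = cols.get("mean") or cols.get("estimate")
        if mean_col is None or "se" not in cols:
            raise MetaError(f"row {label!r}: need either (r, n) or (mean, se) fields")
        effects.append(
            EffectSize(
                study_id=study_id, kind="mean",
                estimate=float(row[mean_col]), se=float(row[cols["se"]]), label=label,
            )
        )
    return effects


def meta_table(study_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pool every effect label shared across the per-study tables.

    Returns one row per label with each study's estimate/SE, the pooled
    estimate, 95% CI, z, p, and — for correlation effects — the pooled
    estimate back-transformed to the r scale. Correlation effects are
    reported on the Fisher-z scale, matching the published presentation.
    """
    per_study: dict[str, list[EffectSize]] = {
        sid: effects_from_study_frame(sid, tbl) for sid, tbl in study_tables.items()
    }
    order: list[str] = []
    for effects in per_study.values():
        for e in effects:
            if e.label not in order:
                order.append(e.label)

    rows = []
    for label in order:
        group = [e for effects in per_study.values() for e in effects if e.label == label]
        pooled = pool_fixed(group)
        row: dict[str, object] = {"label": label, "kind": pooled.kind}
        for e in group:
            row[f"estimate_{e.study_id}"] = e.estimate
            row[f"se_{e.study_id}"] = e.se
        row.update(
            pooled_estimate=pooled.pooled_estimate,
            pooled_se=pooled.pooled_se,
            ci_low=pooled.ci_low,
            ci_high=pooled.ci_high,
            z=pooled.z_stat,
            p=pooled.p,
            pooled_r=inv_fisher_z(pooled.pooled_estimate) if pooled.kind == "fisher_z" else np.nan,
        )
        rows.append(row)
    return pd.DataFrame(rows)
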