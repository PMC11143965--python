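"""Mixture-null analysis of secreted-analyte panels.

The same virtual-coculture idea applied to protein concentrations: for each
real coculture with SC fraction p, the no-interaction expectation of an
analyte is the linear mixture ``p * c_SC + (1 - p) * c_FB`` of its single-
culture concentrations. Real and virtual values are then compared per analyte
with a one-tailed paired t test (default direction: real > virtual).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SecretomePanel, validate_composition
from .errors import ReferenceError_, TestError

__all__ = ["build_virtual_secretome", "paired_one_tailed_t", "analyte_report"]


def build_virtual_secretome(
    singles: SecretomePanel, compositions: pd.DataFrame
) -> SecretomePanel:
    """Virtual coculture concentrations ``v = p*c_SC + (1-p)*c_FB``.

    NaN in either contributing single propagates to the virtual value.
    Output columns are named ``virtual:<coculture_id>``.
    """
    validate_composition(compositions)
    columns, meta = {}, []
    for row in compositions.itertuples(index=False):
        for ref in (row.sc_culture_id, row.fb_culture_id):
            if ref not in singles.values.columns:
                raise ReferenceError_(
                    f"composition row {row.coculture_id!r} references missing single {ref!r}"
                )
        p = float(row.sc_fraction)
        vid = f"virtual:{row.coculture_id}"
        columns[vid] = (
            p * singles.values[row.sc_culture_id]
            + (1.0 - p) * singles.values[row.fb_culture_id]
        )
        meta.append(
            {"sample_id": vid, "role": "virtual", "pair_id": row.coculture_id,
             "sc_culture_id": row.sc_culture_id, "fb_culture_id": row.fb_culture_id}
        )
    values = pd.DataFrame(columns, index=singles.values.index)
    return SecretomePanel(values, pd.DataFrame(meta).set_index("sample_id")).validate()


def paired_one_tailed_t(real, virtual, alternative: str = "greater") -> tuple[float, float]:
    """One-tailed paired t test on ``d = real - virtual``.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with n-1 degrees of freedom; NaN pairs
    are dropped first. An exactly identical pair of vectors is the degenerate
    no-effect case and returns ``(0.0, 0.5)``; a zero-variance difference with
    nonzero mean raises :class:`TestError`.
    """
    if alternative not in ("greater", "less"):
        raise TestError(f"unknown alternative {alternative!r}")
    real = np.asarray(real, dtype=float)
    virtual = np.asarray(virtual, dtype=float)
    if real.shape != virtual.shape:
        raise TestError("paired vectors must have equal length")
    ok = ~(np.isnan(real) | np.isnan(virtual))
    d = real[ok] - virtual[ok]
    if d.size < 2:
        raise TestError(f"need >= 2 complete pairs, got {d.size}")
    if np.all(d == 0):
        return 0.0, 0.5
    if d.std(ddof=1) == 0:
        raise TestError("zero difference variance with nonzero mean: t undefined")
    res = stats.ttest_rel(real[ok], virtual[ok], alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def analyte_report(
    panel: SecretomePanel,
    analytes=None,
    alternative: str = "greater",
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-analyte paired real-vs-virtual test table.

    ``panel`` must contain matched real and virtual samples (pair ids).
    Analytes without enough complete pairs, or with degenerate differences,
    get NaN statistics and are not flagged. Unadjusted p-values drive the
    ``significant`` flag; set ``adjust`` for an additional BH column.
    """
    real_ids = panel.samples_with_role("real")
    pair_of = panel.samples["pair_id"]
    virtual_by_pair = {
        pair_of[sid]: sid for sid in panel.samples_with_role("virtual")
    }
    pairs = [(r, virtual_by_pair[pair_of[r]]) for r in real_ids if pair_of[r] in virtual_by_pair]
    if not pairs:
        raise TestError("panel has no matched real/virtual pairs")
    r_cols = [a for a, _ in pairs]
    v_cols = [b for _, b in pairs]

    names = list(panel.values.index) if analytes is None else list(analytes)
    rows = []
    for name in names:
        real = panel.values.loc[name, r_cols].to_numpy(dtype=float)
        virt = panel.values.loc[name, v_cols].to_numpy(dtype=float)
        ok = ~(np.isnan(real) | np.isnan(virt))
        row = {
            "analyte": name,
            "n_pairs": int(ok.sum()),
            "mean_real": float(np.nanmean(real)) if ok.any() else np.nan,
            "mean_virtual": float(np.nanmean(virt)) if ok.any() else np.nan,
            "t": np.nan,
            "pvalue": np.nan,
            "significant": False,
        }
        try:
            t, p = paired_one_tailed_t(real, virt, alternative)
            row.update(t=t, pvalue=p, significant=bool(p <= alpha))
        except TestError:
            pass
        rows.append(row)
    table = pd.DataFrame(rows).set_index("analyte")
    if adjust:
        from .de import adjust_bh

        table["padj"] = adjust_bh(table["pvalue"].to_numpy())
    return table
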