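"""qPCR and colony-count quantification formulas.

Three explicit calculations used around the L1 retrotransposition experiments:

* RIP-qPCR fold enrichment — how much L1 mRNA co-precipitates with ORF1p,
  normalized to a diluted input fraction and to immunoprecipitation
  efficiency::

      ΔCt(normalized RIP) = Ct(RIP) − [Ct(Input) − log2(input dilution factor)]
      ΔΔCt                = ΔCt(experimental) − ΔCt(control)
      fold enrichment     = 2^(−ΔΔCt)

  with the fold optionally adjusted by the ratio of ORF1p protein recovered
  in the two IP fractions; the control group is normalized to 1.

* Relative expression by the 2^(−ΔΔCt) method against a reference gene.

* Relative retrotransposition activity — G418-resistant colonies from
  L1-neo-transfected cells divided by those from empty-vector controls.

Ct tables are tidy DataFrames with columns ``sample, group, fraction, target,
ct, dilution_factor`` (``group`` in {experimental, control}; ``fraction`` in
{RIP, input}; ``dilution_factor`` required on input rows).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CT_COLUMNS",
    "rip_fold_enrichment",
    "ddct_expression",
    "retro_activity",
]

CT_COLUMNS = ("sample", "group", "fraction", "target", "ct", "dilution_factor")

GROUPS = ("experimental", "control")


def _check_table(table: pd.DataFrame, required: tuple[str, ...]) -> None:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")


def _mean_ct(table: pd.DataFrame, group: str, fraction: str, target: str) -> float:
    cell = table[
        (table["group"] == group)
        & (table["fraction"] == fraction)
        & (table["target"] == target)
    ]
    if cell.empty:
        raise ValueError(f"no Ct values for cell (group={group}, fraction={fraction}, target={target})")
    return float(cell["ct"].mean())


def _mean_normalized_input(table: pd.DataFrame, group: str, target: str) -> float:
    cell = table[
        (table["group"] == group)
        & (table["fraction"] == "input")
        & (table["target"] == target)
    ]
    if cell.empty:
        raise ValueError(f"no Ct values for cell (group={group}, fraction=input, target={target})")
    dil = cell["dilution_factor"].astype(float)
    if (dil <= 0).any() or dil.isna().any():
        raise ValueError(f"nonpositive or missing input dilution factor for (group={group}, target={target})")
    # Ct(Input) - log2(dilution factor), replicates averaged after correction
    return float((cell["ct"].astype(float) - np.log2(dil)).mean())


def rip_fold_enrichment(
    table: pd.DataFrame,
    ip_protein_ratio: float = 1.0,
    *,
    adjust_direction: str = "divide",
) -> pd.DataFrame:
    """RIP-qPCR fold enrichment per target, with IP-efficiency adjustment.

    ``ip_protein_ratio`` is ORF1p(IP, experimental) / ORF1p(IP, control); the
    fold is divided by it by default (``adjust_direction="multiply"`` selects
    the reciprocal reading).  Replicate Ct values are averaged before the Δ
    computations.  Returns one row per target with ΔCt per group, ΔΔCt, fold
    enrichment 2^(−ΔΔCt) and the adjusted fold; the control fold is 1 by
    construction.
    """
    _check_table(table, ("group", "fraction", "target", "ct", "dilution_factor"))
    if ip_protein_ratio <= 0:
        raise ValueError("ip_protein_ratio must be positive")
    if adjust_direction not in ("divide", "multiply"):
        raise ValueError("adjust_direction must be 'divide' or 'multiply'")
    frac = set(table["fraction"].unique())
    if not frac <= {"RIP", "input"}:
        raise ValueError(f"unknown fraction labels: {sorted(frac - {'RIP', 'input'})}")

    rows = []
    for target in sorted(table["target"].unique()):
        dct = {}
        for group in GROUPS:
            ct_rip = _mean_ct(table, group, "RIP", target)
            input_norm = _mean_normalized_input(table, group, target)
            dct[group] = ct_rip - input_norm
        ddct = dct["experimental"] - dct["control"]
        fold = 2.0 ** (-ddct)
        if adjust_direction == "divide":
            adjusted = fold / ip_protein_ratio
        else:
            adjusted = fold * ip_protein_ratio
        rows.append(
            {
                "target": target,
                "delta_ct_experimental": dct["experimental"],
                "delta_ct_control": dct["control"],
                "delta_delta_ct": ddct,
                "fold_enrichment": fold,
                "adjusted_fold": adjusted,
                "control_fold": 1.0,
            }
        )
    return pd.DataFrame(rows)


def ddct_expression(
    table: pd.DataFrame,
    reference_target: str,
    *,
    control_group: str = "control",
) -> pd.DataFrame:
    """Relative expression by the 2^(−ΔΔCt) method.

    Per sample, ΔCt = Ct(target) − Ct(reference); ΔΔCt is taken against the
    control group's mean ΔCt for that target, so the control group's mean
    expression is 1.  Requires the reference target in every sample.  Returns
    one row per (target, group, sample) with the relative expression.
    """
    _check_table(table, ("sample", "group", "target", "ct"))
    ref = table[table["target"] == reference_target]
    if ref.empty:
        raise ValueError(f"reference target {reference_target!r} not present")
    ref_ct = ref.groupby("sample")["ct"].mean()

    rows = []
    targets = [t for t in sorted(table["target"].unique()) if t != reference_target]
    for target in targets:
        sub = table[table["target"] == target]
        missing_ref = set(sub["sample"]) - set(ref_ct.index)
        if missing_ref:
            raise ValueError(
                f"reference target {reference_target!r} missing for samples {sorted(missing_ref)}"
            )
        dct = sub.groupby(["group", "sample"])["ct"].mean() - ref_ct
        control_dcts = dct.loc[control_group] if control_group in dct.index.get_level_values(0) else None
        if control_dcts is None:
            raise ValueError(f"no samples in control group {control_group!r} for target {target!r}")
        baseline = float(control_dcts.mean())
        for (group, sample), value in dct.items():
            rows.append(
                {
                    "target": target,
                    "group": group,
                    "sample": sample,
                    "delta_ct": float(value),
                    "delta_delta_ct": float(value - baseline),
                    "relative_expression": 2.0 ** (-(value - baseline)),
                }
            )
    return pd.DataFrame(rows)


def retro_activity(
    counts: pd.DataFrame,
    *,
    normalize_to: str | None = None,
) -> pd.DataFrame:
    """Relative L1 retrotransposition activity from colony counts.

    ``counts`` has one row per condition with columns ``condition,
    colonies_l1neo, colonies_control``; activity = colonies(L1-neo) /
    colonies(empty vector).  With ``normalize_to`` set, activities are
    rescaled so the named condition equals 1.
    """
    _check_table(counts, ("condition", "colonies_l1neo", "colonies_control"))
    for col in ("colonies_l1neo", "colonies_control"):
        vals = counts[col]
        if (vals < 0).any() or (vals != vals.astype(int)).any():
            raise ValueError(f"{col} must contain nonnegative integer counts")
    if (counts["colonies_control"] == 0).any():
        bad = counts.loc[counts["colonies_control"] == 0, "condition"].tolist()
        raise ValueError(f"zero control colonies for conditions {bad}: ratio undefined")
    out = counts.copy()
    out["activity"] = out["colonies_l1neo"] / out["colonies_control"]
    if normalize_to is not None:
        ref = out.loc[out["condition"] == normalize_to, "activity"]
        if ref.empty:
            raise ValueError(f"condition {normalize_to!r} not found")
        out["relative_activity"] = out["activity"] / float(ref.iloc[0])
    return out
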