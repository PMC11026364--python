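"""Cohort-level comparison batteries over connectivity profiles.

Two standard designs:

* **genotype × age battery** — four group pairs (WT vs 5xFAD within each
  age; young vs middle within each genotype) × two metrics (CSI, PI) × the
  21 named regions. Within each (pair × metric) family of 21 p-values, the
  Benjamini–Hochberg step-up procedure controls the FDR at q = 0.05.
* **sex battery** — male vs female within each genotype × age group, per
  region and metric. Unadjusted by default (configurable): the source
  analyses applied FDR control only to the genotype/age families.

All tests are two-sided exact Wilcoxon rank-sum tests on per-animal index
values. Reported direction is the sign of the group-mean difference (a − b).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import summarize_group
from .regions import CANONICAL_REGIONS
from .stats import bh_adjust, rank_sum_test, star_level

__all__ = [
    "ComparisonDesign",
    "GENOTYPE_AGE_PAIRS",
    "SEX_GROUPS",
    "run_genotype_age_comparisons",
    "run_sex_comparisons",
    "render_tables",
]

GroupKey = tuple[str, str]  # (genotype, age_group)

GENOTYPE_AGE_PAIRS: tuple[tuple[GroupKey, GroupKey], ...] = (
    (("WT", "young"), ("5xFAD", "young")),
    (("WT", "middle"), ("5xFAD", "middle")),
    (("WT", "young"), ("WT", "middle")),
    (("5xFAD", "young"), ("5xFAD", "middle")),
)

SEX_GROUPS: tuple[GroupKey, ...] = (
    ("WT", "young"), ("WT", "middle"), ("5xFAD", "young"), ("5xFAD", "middle"),
)


@dataclass(frozen=True)
class ComparisonDesign:
    """Parameters of a comparison battery."""

    metrics: tuple[str, ...] = ("CSI", "PI")
    regions: tuple[str, ...] = CANONICAL_REGIONS
    fdr_q: float = 0.05
    adjust: bool = True

    def __post_init__(self):
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must lie in (0, 1)")
        for m in self.metrics:
            if m not in ("CSI", "PI"):
                raise ValueError(f"unknown metric {m!r}")


def _group_mask(profiles: pd.DataFrame, key: GroupKey, sex: str | None = None) -> np.ndarray:
    mask = (profiles["genotype"] == key[0]) & (profiles["age_group"] == key[1])
    if sex is not None:
        mask &= profiles["sex"] == sex
    return mask.to_numpy()


def _pair_label(a: GroupKey, b: GroupKey) -> str:
    return f"{a[0]} {a[1]} vs {b[0]} {b[1]}"


def _one_family(
    sub_a: pd.DataFrame, sub_b: pd.DataFrame, metric: str, pair: str,
    design: ComparisonDesign,
) -> pd.DataFrame:
    """Rank-sum test per region for one (pair × metric) family."""
    rows = []
    for region in design.regions:
        col = f"{metric.lower()}_{region}"
        va = sub_a[col].to_numpy(dtype=float)
        vb = sub_b[col].to_numpy(dtype=float)
        res = rank_sum_test(va, vb)
        rows.append({
            "metric": metric,
            "region": region,
            "pair": pair,
            "n_a": len(va),
            "n_b": len(vb),
            "raw_p": res.p_two_sided,
            "direction": int(np.sign(va.mean() - vb.mean())),
            "method": res.method,
        })
    fam = pd.DataFrame(rows)
    fam["adj_p"] = bh_adjust(fam["raw_p"].to_numpy()) if design.adjust else fam["raw_p"]
    fam["stars"] = [star_level(p) if p <= 0.05 else "ns" for p in fam["adj_p"]]
    return fam


def run_genotype_age_comparisons(
    profiles: pd.DataFrame, design: ComparisonDesign | None = None
) -> pd.DataFrame:
    """Run the four genotype/age group-pair comparisons for CSI and PI.

    BH adjustment is applied within each (pair × metric) family of
    ``len(design.regions)`` regions. Output rows follow the region order of
    the vocabulary, grouped by metric then pair.
    """
    design = design or ComparisonDesign()
    out = []
    for metric in design.metrics:
        for a, b in GENOTYPE_AGE_PAIRS:
            sub_a = profiles.loc[_group_mask(profiles, a)]
            sub_b = profiles.loc[_group_mask(profiles, b)]
            if sub_a.empty or sub_b.empty:
                raise ValueError(f"empty group in pair {_pair_label(a, b)}")
            out.append(_one_family(sub_a, sub_b, metric, _pair_label(a, b), design))
    return pd.concat(out, ignore_index=True)


def run_sex_comparisons(
    profiles: pd.DataFrame, design: ComparisonDesign | None = None
) -> pd.DataFrame:
    """Male vs female comparison within each genotype × age group.

    Unadjusted by default; pass a design with ``adjust=True`` to apply BH
    within each (group × metric) family.
    """
    design = design or ComparisonDesign(adjust=False)
    out = []
    for metric in design.metrics:
        for group in SEX_GROUPS:
            sub_m = profiles.loc[_group_mask(profiles, group, sex="M")]
            sub_f = profiles.loc[_group_mask(profiles, group, sex="F")]
            if sub_m.empty or sub_f.empty:
                raise ValueError(f"empty sex subgroup in {group}")
            pair = f"{group[0]} {group[1]} M vs F"
            out.append(_one_family(sub_m, sub_f, metric, pair, design))
    return pd.concat(out, ignore_index=True)


def render_tables(
    profiles: pd.DataFrame,
    genotype_age_results: pd.DataFrame | None,
    sex_results: pd.DataFrame | None,
    out_dir,
) -> list[Path]:
    """Write publication-layout CSV tables; returns the written paths.

    * ``group_summary.csv`` — per-group mean ± SEM blocks (CSI, PI, cohort
      rows), four genotype×age columns.
    * ``sex_summary.csv`` — likewise for the eight sex-stratified groups.
    * ``comparisons_genotype_age.csv`` / ``comparisons_sex.csv`` — region
      rows × pair columns with p + star pairs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _summary_table(keys: list[dict], labels: list[str]) -> pd.DataFrame:
        blocks = []
        for key, label in zip(keys, labels):
            s = summarize_group(profiles, key)
            s = s.rename(columns={"mean": f"{label} mean", "sem": f"{label} SEM"})
            blocks.append(s.set_index(["block", "row"]))
        return pd.concat(blocks, axis=1).reset_index()

    group_keys = [{"genotype": g, "age_group": a} for (g, a) in SEX_GROUPS]
    group_labels = [f"{g} {a}" for (g, a) in SEX_GROUPS]
    path = out_dir / "group_summary.csv"
    _summary_table(group_keys, group_labels).to_csv(path, index=False)
    written.append(path)

    sex_keys, sex_labels = [], []
    for (g, a) in SEX_GROUPS:
        for s in ("M", "F"):
            sex_keys.append({"genotype": g, "age_group": a, "sex": s})
            sex_labels.append(f"{g} {a} {s}")
    present = [
        (k, l) for k, l in zip(sex_keys, sex_labels)
        if ((profiles["genotype"] == k["genotype"])
            & (profiles["age_group"] == k["age_group"])
            & (profiles["sex"] == k["sex"])).any()
    ]
    if present:
        path = out_dir / "sex_summary.csv"
        _summary_table([k for k, _ in present], [l for _, l in present]).to_csv(path, index=False)
        written.append(path)

    for results, name in (
        (genotype_age_results, "comparisons_genotype_age.csv"),
        (sex_results, "comparisons_sex.csv"),
    ):
        if results is None or results.empty:
            continue
        wide = results.pivot(index=["metric", "region"], columns="pair",
                             values=["adj_p", "stars"])
        wide = wide.swaplevel(axis=1).sort_index(axis=1, level=0)
        wide.columns = [f"{pair} [{what}]" for pair, what in wide.columns]
        wide = wide.reindex(
            pd.MultiIndex.from_product([["CSI", "PI"], list(CANONICAL_REGIONS)],
                                       names=["metric", "region"])
        ).reset_index()
        path = out_dir / name
        wide.to_csv(path, index=False)
        written.append(path)

    path = out_dir / "per_mouse_profiles.csv"
    profiles.sort_values("mouse_id", kind="mergesort").to_csv(path, index=False)
    written.append(path)
    return written
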