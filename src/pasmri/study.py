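"""End-to-end haemorrhage-risk study on a (synthetic or supplied) cohort.

``PASStudy`` is the model object: it holds a per-patient cohort table and
the analysis configuration.  ``fit()`` runs the full published analysis
shape — normality-gated group summaries, Spearman correlation block,
contingency-table tests, ROC curves for predicting massive (>= 1000 ml)
and severe (>= 2000 ml) haemorrhage, and the two-reader agreement block —
and returns a ``PASStudyResults`` carrying every statistic together with
the data that produced it, a text ``summary()`` and a ``save()`` writer.

Example
-------
>>> from pasmri.study import PASStudy
>>> res = PASStudy.from_simulation(seed=7).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as st
from .cohort import CohortConfig, GROUP_LABELS, simulate_cohort

SUMMARY_VARIABLES = ("ebl_ml", "rbc_units", "dib_volume_mm3")
CORRELATION_PAIRS = (
    ("mt_grade", "ebl_ml"),
    ("dib_volume_mm3", "ebl_ml"),
    ("mt_grade", "rbc_units"),
    ("dib_volume_mm3", "rbc_units"),
    ("rbc_units", "ebl_ml"),
    ("depth_code", "ebl_ml"),
    ("depth_code", "rbc_units"),
    ("depth_code", "dib_volume_mm3"),
    ("depth_code", "mt_grade"),
)


@dataclass
class StudyConfig:
    """Analysis settings: normality gate and ROC event thresholds."""

    normality_alpha: float = 0.05
    roc_thresholds_ml: tuple = (1000.0, 2000.0)

    def __post_init__(self):
        if not 0 < self.normality_alpha < 1:
            raise ValueError("normality_alpha must be in (0, 1)")


class PASStudy:
    """Study model built from a per-patient cohort table.

    The table needs the columns produced by
    :func:`pasmri.cohort.simulate_cohort`; externally supplied tables with
    the same column dictionary work identically.
    """

    def __init__(self, cohort: pd.DataFrame, config: Optional[StudyConfig] = None):
        required = {"mt_grade", "dib_volume_mm3", "ebl_ml", "group",
                    "rbc_units", "previa", "depth_code"}
        missing = required - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
        self.cohort = cohort.reset_index(drop=True)
        self.config = config or StudyConfig()

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame,
                       config: Optional[StudyConfig] = None) -> "PASStudy":
        return cls(cohort, config)

    @classmethod
    def from_csv(cls, path, config: Optional[StudyConfig] = None) -> "PASStudy":
        return cls(pd.read_csv(path), config)

    @classmethod
    def from_simulation(cls, cohort_config: Optional[CohortConfig] = None,
                        seed: Optional[int] = None,
                        config: Optional[StudyConfig] = None) -> "PASStudy":
        return cls(simulate_cohort(cohort_config, seed=seed), config)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "PASStudyResults":
        df = self.cohort
        if len(df) == 0:
            raise ValueError("empty cohort: nothing to analyse")
        groups = [df[df["group"] == g] for g in GROUP_LABELS]
        group_sizes = {g: int(len(sub)) for g, sub in zip(GROUP_LABELS, groups)}

        summaries = [self._summarise_variable(df, groups, var)
                     for var in SUMMARY_VARIABLES]
        correlations = [
            {"x": x, "y": y, **dataclasses.asdict(st.spearman(df[x], df[y]))}
            for x, y in CORRELATION_PAIRS
        ]
        contingency = self._contingency_block(df)
        roc = self._roc_block(df)
        agreement = self._agreement_block(df)

        return PASStudyResults(
            cohort=df,
            config=self.config,
            group_sizes=group_sizes,
            group_summaries=summaries,
            correlations=correlations,
            contingency=contingency,
            roc=roc,
            agreement=agreement,
        )

    def _summarise_variable(self, df, groups, var):
        x = df[var].to_numpy(dtype=float)
        entry = {"variable": var}
        try:
            ks = st.ks_normality(x)
            normal = ks.p_value >= self.config.normality_alpha
            entry["ks_p"] = ks.p_value
        except ValueError as exc:
            normal = False
            entry["ks_p"] = None
            entry["note"] = f"normality test unavailable ({exc})"
        entry["normal"] = bool(normal)
        per_group = {}
        for g, sub in zip(GROUP_LABELS, groups):
            v = sub[var].to_numpy(dtype=float)
            if len(v) == 0:
                per_group[g] = None
            elif normal:
                per_group[g] = {"mean": float(v.mean()),
                                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0}
            else:
                q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
                per_group[g] = {"median": float(med), "q1": float(q1), "q3": float(q3)}
        entry["per_group"] = per_group
        vals = [sub[var].to_numpy(dtype=float) for sub in groups]
        if any(len(v) < 2 for v in vals):
            entry["test"] = None
            entry["note"] = "group with < 2 patients: between-group test skipped"
        else:
            test = st.oneway_anova(vals) if normal else st.kruskal_wallis(vals)
            entry["test"] = dataclasses.asdict(test)
        return entry

    def _contingency_block(self, df):
        block = {}
        previa = pd.crosstab(df["group"], df["previa"])
        previa = previa.reindex(index=[g for g in GROUP_LABELS if g in previa.index])
        previa = previa.loc[:, previa.sum(axis=0) > 0]
        previa = previa.loc[previa.sum(axis=1) > 0, :]
        block["attachment_by_group"] = self._table_entry(previa)
        if "haemostasis" in df.columns:
            hae = pd.crosstab(df["haemostasis"], df["group"])
            hae = hae.loc[hae.sum(axis=1) > 0, [g for g in GROUP_LABELS if g in hae.columns]]
            block["haemostasis_by_group"] = self._table_entry(hae)
            balloon = df["haemostasis"] == "balloon_occlusion"
            exmbl = df["group"] == "ex-MBL"
            two = np.array([
                [int((balloon & exmbl).sum()), int((~balloon & exmbl).sum())],
                [int((balloon & ~exmbl).sum()), int((~balloon & ~exmbl).sum())],
            ])
            block["balloon_exmbl_vs_rest"] = self._table_entry(
                pd.DataFrame(two, index=["ex-MBL", "others"],
                             columns=["balloon", "no_balloon"]),
                continuity_correction=True)
        return block

    @staticmethod
    def _table_entry(table: pd.DataFrame, continuity_correction: bool = False):
        entry = {"rows": list(map(str, table.index)),
                 "cols": list(map(str, table.columns)),
                 "counts": table.to_numpy().tolist()}
        try:
            res = st.chi_square(table.to_numpy(), continuity_correction)
            entry["test"] = dataclasses.asdict(res)
        except ValueError as exc:
            entry["test"] = None
            entry["note"] = str(exc)
        return entry

    def _roc_block(self, df):
        block = {}
        for thr in self.config.roc_thresholds_ml:
            event = (df["ebl_ml"] >= thr).astype(int).to_numpy()
            tag = f"ge{int(thr)}"
            for name, scores in (
                    # high grade predicts *less* bleeding: sign-flip
                    ("mt_grade", -df["mt_grade"].to_numpy(dtype=float)),
                    ("dib_volume", df["dib_volume_mm3"].to_numpy(dtype=float))):
                key = f"{name}_{tag}"
                try:
                    roc = st.roc_auc(scores, event)
                    block[key] = {
                        "auc": roc.auc,
                        "n_pos": roc.n_pos, "n_neg": roc.n_neg,
                        "sensitivity": roc.sensitivity.tolist(),
                        "fpr": roc.fpr.tolist(),
                        "thresholds": roc.thresholds.tolist(),
                    }
                except ValueError as exc:
                    block[key] = {"auc": None, "note": str(exc)}
        return block

    def _agreement_block(self, df):
        block = {}
        if {"grade_r1", "grade_r2"} <= set(df.columns):
            block["mt_grade_kappa"] = dataclasses.asdict(
                st.cohens_kappa(df["grade_r1"], df["grade_r2"]))
        if {"dib_r1_mm3", "dib_r2_mm3"} <= set(df.columns):
            block["dib_volume_icc"] = dataclasses.asdict(
                st.icc(df[["dib_r1_mm3", "dib_r2_mm3"]].to_numpy()))
        return block


@dataclass
class PASStudyResults:
    """Fitted study: every block keeps the data needed to recompute it."""

    cohort: pd.DataFrame
    config: StudyConfig
    group_sizes: dict
    group_summaries: list
    correlations: list
    contingency: dict
    roc: dict
    agreement: dict

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        lines = []
        n = len(self.cohort)
        sizes = ", ".join(f"{g}={self.group_sizes[g]}" for g in GROUP_LABELS)
        lines.append("Haemorrhage-risk study summary")
        lines.append("=" * 64)
        lines.append(f"Patients: {n}  ({sizes})")
        lines.append("")
        lines.append("Group summaries (mean+/-sd if normal, else median (Q1, Q3)):")
        for entry in self.group_summaries:
            var = entry["variable"]
            style = "normal" if entry["normal"] else "non-normal"
            test = entry.get("test")
            p = f"p={test['p_value']:.4g} [{test['method']}]" if test else "test skipped"
            lines.append(f"  {var} ({style}): {p}")
            for g in GROUP_LABELS:
                cell = entry["per_group"].get(g)
                if cell is None:
                    desc = "n/a"
                elif "mean" in cell:
                    desc = f"{cell['mean']:.1f} +/- {cell['sd']:.1f}"
                else:
                    desc = f"{cell['median']:.2f} ({cell['q1']:.2f}, {cell['q3']:.2f})"
                lines.append(f"    {g:7s} {desc}")
        lines.append("")
        lines.append("Spearman correlations:")
        for c in self.correlations:
            lines.append(f"  {c['x']:16s} vs {c['y']:12s} rho={c['rho']:+.3f}  p={c['p_value']:.4g}")
        lines.append("")
        lines.append("Contingency tests:")
        for key, entry in self.contingency.items():
            t = entry.get("test")
            desc = (f"chi2={t['statistic']:.3f}, df={t['df']}, p={t['p_value']:.4g} "
                    f"[{t['method']}]") if t else entry.get("note", "unavailable")
            lines.append(f"  {key}: {desc}")
        lines.append("")
        lines.append("ROC (higher score predicts the event):")
        for key, entry in self.roc.items():
            auc = entry.get("auc")
            lines.append(f"  {key:22s} AUC={auc:.3f}" if auc is not None
                         else f"  {key:22s} {entry.get('note','')}")
        lines.append("")
        lines.append("Two-reader agreement:")
        for key, entry in self.agreement.items():
            lines.append(f"  {key}: {entry['value']:.3f} [{entry['method']}]")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_patients": int(len(self.cohort)),
            "group_sizes": self.group_sizes,
            "group_summaries": self.group_summaries,
            "correlations": self.correlations,
            "contingency": self.contingency,
            "roc": {k: {kk: vv for kk, vv in v.items()
                        if kk in ("auc", "n_pos", "n_neg", "note")}
                    for k, v in self.roc.items()},
            "agreement": self.agreement,
        }

    # -- persistence ----------------------------------------------------------

    def save(self, outdir, plots: bool = True) -> list:
        """Write CSV tables, a JSON summary, ROC point CSVs and figures.

        CSV/JSON output is deterministically formatted: re-running with the
        same cohort produces byte-identical text files.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def _w(path, text):
            path.write_text(text)
            written.append(path)

        self.cohort.to_csv(outdir / "cohort.csv", index=False, float_format="%.6f")
        written.append(outdir / "cohort.csv")

        rows = []
        for entry in self.group_summaries:
            for g in GROUP_LABELS:
                cell = entry["per_group"].get(g) or {}
                rows.append({
                    "variable": entry["variable"], "group": g,
                    "normal": entry["normal"],
                    **{k: f"{v:.6f}" for k, v in cell.items()},
                    "p_value": (f"{entry['test']['p_value']:.6g}"
                                if entry.get("test") else ""),
                })
        pd.DataFrame(rows).to_csv(outdir / "group_summaries.csv", index=False)
        written.append(outdir / "group_summaries.csv")

        corr = pd.DataFrame(self.correlations)
        corr.to_csv(outdir / "correlations.csv", index=False, float_format="%.6g")
        written.append(outdir / "correlations.csv")

        _w(outdir / "summary.json",
           json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_json_default))

        for key, entry in self.roc.items():
            if entry.get("auc") is None:
                continue
            pts = pd.DataFrame({"threshold": [np.inf] + list(entry["thresholds"]),
                                "fpr": entry["fpr"],
                                "sensitivity": entry["sensitivity"]})
            pts.to_csv(outdir / f"roc_{key}.csv", index=False, float_format="%.6g")
            written.append(outdir / f"roc_{key}.csv")

        if plots:
            written.extend(self._plots(outdir))
        return written

    def _plots(self, outdir: Path) -> list:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        written = []
        fig, axes = plt.subplots(1, 2, figsize=(9, 4.2), sharey=True)
        for ax, tag, title in zip(axes,
                                  [f"ge{int(t)}" for t in self.config.roc_thresholds_ml],
                                  [f"EBL >= {int(t)} ml" for t in self.config.roc_thresholds_ml]):
            for name, label in (("mt_grade", "MT grade (sign-flipped)"),
                                ("dib_volume", "DIB volume")):
                entry = self.roc.get(f"{name}_{tag}", {})
                if entry.get("auc") is None:
                    continue
                ax.plot(entry["fpr"], entry["sensitivity"], marker=".",
                        label=f"{label} (AUC={entry['auc']:.3f})")
            ax.plot([0, 1], [0, 1], "k:", lw=0.8)
            ax.set_xlabel("1 - specificity")
            ax.set_title(title)
            ax.legend(loc="lower right", fontsize=8)
        axes[0].set_ylabel("sensitivity")
        fig.tight_layout()
        fig.savefig(outdir / "roc_curves.png", dpi=120)
        plt.close(fig)
        written.append(outdir / "roc_curves.png")

        # EBL by MT grade: box plus jittered scatter
        fig, ax = plt.subplots(figsize=(5, 4))
        data = [self.cohort.loc[self.cohort["mt_grade"] == g, "ebl_ml"].to_numpy()
                for g in (0, 1, 2)]
        ax.boxplot(data, tick_labels=["G0", "G1", "G2"], showfliers=False)
        rng = np.random.default_rng(0)  # jitter only, cosmetic
        for i, d in enumerate(data, start=1):
            ax.plot(i + rng.uniform(-0.12, 0.12, len(d)), d, "o", ms=3, alpha=0.5)
        ax.set_xlabel("MT grade")
        ax.set_ylabel("estimated blood loss (ml)")
        fig.tight_layout()
        fig.savefig(outdir / "ebl_by_grade.png", dpi=120)
        plt.close(fig)
        written.append(outdir / "ebl_by_grade.png")
        return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_study(cohort_config: Optional[CohortConfig] = None,
              study_config: Optional[StudyConfig] = None,
              seed: Optional[int] = None) -> PASStudyResults:
    """Simulate a cohort and fit the full study in one call."""
    return PASStudy.from_simulation(cohort_config, seed=seed, config=study_config).fit()


def write_report(results: PASStudyResults, outdir, plots: bool = True) -> list:
    """Write the report files for a fitted study (see ``PASStudyResults.save``)."""
    return results.save(outdir, plots=plots)


def write_empty_report(outdir) -> list:
    """Header-only CSVs for an empty cohort (callers should signal the
    empty input through their exit status)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    headers = {
        "cohort.csv": "patient_id,pas_depth,depth_code,mt_grade,grade_r1,grade_r2,"
                      "dib_volume_true_mm3,dib_r1_mm3,dib_r2_mm3,dib_volume_mm3,"
                      "ebl_ml,group,rbc_units,previa,haemostasis\n",
        "group_summaries.csv": "variable,group,normal,p_value\n",
        "correlations.csv": "x,y,rho,p_value,n,method\n",
    }
    for name, header in headers.items():
        p = outdir / name
        p.write_text(header)
        paths.append(p)
    return paths
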