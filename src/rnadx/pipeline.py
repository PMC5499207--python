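"""Cohort-level orchestration of the three diagnostic strategies.

``run_all`` reads a cohort directory (count matrix, sample annotation,
junction table, exon GTF, variant allele counts), runs aberrant
expression, aberrant splicing (including the splice-site strength
mixture) and mono-allelic expression for every patient, and writes
per-strategy tables, a merged candidate table and a summary with
per-strategy medians and 90th percentiles across samples.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .expression import ExpressionOutlierModel
from .mae import MAEModel
from .psi_mixture import PsiMixture, COMPONENTS
from .splicing import (
    SplicingOutlierModel,
    private_exon_weak_enrichment,
    psi_site_observations,
)

__all__ = ["PipelineThresholds", "OutlierReport", "run_all"]


@dataclass
class PipelineThresholds:
    """All calling thresholds in one place (defaults as used throughout:
    adjusted p 0.05, |Z| > 3, allele frequency 0.8, MAF 0.001,
    minclureads 30)."""

    padj: float = 0.05
    zscore: float = 3.0
    mae_af: float = 0.8
    rare_maf: float = 0.001
    min_coverage: int = 10
    min_reads: int = 10
    expression_quantile: float = 0.95
    minclureads: int = 30
    maxintronlen: int = 500_000
    mincluratio: float = 1e-5
    covariates: tuple = ("batch", "sex", "biopsy_site")

    @classmethod
    def from_yaml(cls, path) -> "PipelineThresholds":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class OutlierReport:
    """Merged per-sample candidate events from the three strategies."""

    expression: pd.DataFrame
    splicing: pd.DataFrame
    mae: pd.DataFrame
    site_classes: pd.DataFrame
    candidates: pd.DataFrame
    per_sample: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def summary_text(self) -> str:
        s = self.summary
        lines = ["Cohort outlier report"]
        for key in ("expression", "splicing", "rare_mae"):
            lines.append(
                f"  {key:>10}: median {s['median'][key]:g} per sample, "
                f"90th percentile {s['p90'][key]:g}"
            )
        if s.get("weak_fraction") is not None:
            lines.append(
                f"  private new exons from weak sites: "
                f"{s['weak_fraction']:.2f} ({s['weak_fold']:.1f}-fold vs chance)"
            )
        return "\n".join(lines)


def _check_samples(counts, annotation, junction_samples, variant_samples):
    ref = list(counts.columns)
    problems = []
    for name, got in (
        ("annotation", list(annotation.index)),
        ("junctions", junction_samples),
        ("variants", variant_samples),
    ):
        missing = sorted(set(ref) - set(got))
        extra = sorted(set(got) - set(ref))
        if missing:
            problems.append(f"{name} lacks samples: {', '.join(missing)}")
        if extra:
            problems.append(f"{name} has unknown samples: {', '.join(extra)}")
    if problems:
        raise io.ValidationError("inconsistent sample sets: " + "; ".join(problems))


def run_all(
    in_dir,
    out_dir=None,
    patient: str | None = None,
    thresholds: PipelineThresholds | None = None,
    gene_lists: dict[str, set] | None = None,
    mixture_seed: int = 0,
) -> OutlierReport:
    """Run the three strategies for every (or one) patient.

    ``in_dir`` must contain counts.tsv, annotation.tsv, junctions.tsv,
    exons.gtf and variants.tsv (the layout written by
    :func:`rnadx.simulate.write_cohort`). Writes result TSVs, the merged
    candidate table, a summary JSON and a timestamped log when
    ``out_dir`` is given. ``gene_lists`` maps a label to a set of
    feature ids used to annotate candidates.
    """
    t = thresholds or PipelineThresholds()
    in_dir = Path(in_dir)
    log: list[str] = []

    def note(msg):
        log.append(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")

    note(f"reading cohort from {in_dir}")
    counts = io.read_counts(in_dir / "counts.tsv")
    annotation = io.read_annotation(in_dir / "annotation.tsv")
    junctions = io.read_junction_table(in_dir / "junctions.tsv")
    exons = io.read_gtf_exons(in_dir / "exons.gtf")
    variants_wide = io.read_variants(in_dir / "variants.tsv")
    variants = io.variants_to_long(variants_wide)
    junction_samples = [c for c in junctions.columns if c not in io.JUNCTION_KEY]
    _check_samples(counts, annotation, junction_samples,
                   sorted(variants["sample"].unique()))

    note("aberrant expression: one-vs-rest NB GLM")
    expr_model = ExpressionOutlierModel(
        counts, annotation, min_reads=t.min_reads,
        quantile=t.expression_quantile, covariates=list(t.covariates),
    )
    expr = expr_model.fit(patient=patient).call_outliers(
        padj_threshold=t.padj, z_threshold=t.zscore
    )

    note("aberrant splicing: clustering and Dirichlet-multinomial LRT")
    spl_model = SplicingOutlierModel(
        junctions, annotation, exons,
        minclureads=t.minclureads, maxintronlen=t.maxintronlen,
        mincluratio=t.mincluratio,
    )
    spl_results = spl_model.fit(patient=patient)
    spl_calls = spl_results.call_events(padj_threshold=t.padj)

    note("splice-site strength: beta-binomial mixture EM")
    obs = psi_site_observations(spl_model.junctions, spl_model.flags)
    site_classes = pd.DataFrame()
    weak_fraction = weak_fold = None
    if len(obs) >= 10:
        mix = PsiMixture(obs["n"], obs["N"], obs["s"]).fit(seed=mixture_seed)
        classes, post = mix.classify(obs["n"], obs["N"], obs["s"])
        site_classes = obs[["site", "s", "n", "N"]].copy()
        site_classes["psi"] = site_classes["n"] / site_classes["N"]
        for c, name in enumerate(COMPONENTS):
            site_classes[f"p_{name}"] = post[:, c]
        site_classes["class"] = [COMPONENTS[c] for c in classes]
        class_series = pd.Series(
            site_classes["class"].to_numpy(), index=site_classes["site"]
        )
        weak_fraction, weak_fold = private_exon_weak_enrichment(
            spl_calls, class_series
        )

    note("mono-allelic expression: fixed-dispersion NB test")
    mae_results = MAEModel(variants, min_coverage=t.min_coverage).fit(
        af_threshold=t.mae_af, padj_threshold=t.padj, rare_af=t.rare_maf
    )
    if patient is not None:
        mae_table = mae_results.table[
            mae_results.table["sample"] == str(patient)
        ].reset_index(drop=True)
    else:
        mae_table = mae_results.table

    # merged candidate table
    expr_out = expr[expr["is_outlier"]]
    rare_mae = mae_table[mae_table["is_mae"] & mae_table["is_rare"]]
    cand_frames = [
        pd.DataFrame(
            {
                "sample": expr_out["sample"],
                "strategy": "expression",
                "feature": expr_out["gene"],
                "effect": expr_out["log2fc"],
                "padj": expr_out["padj"],
                "detail": "zscore=" + expr_out["zscore"].round(2).astype(str),
            }
        ),
        pd.DataFrame(
            {
                "sample": spl_calls["sample"],
                "strategy": "splicing",
                "feature": spl_calls["cluster"],
                "effect": np.nan,
                "padj": spl_calls["padj"],
                "detail": spl_calls["event_class"],
            }
        ),
        pd.DataFrame(
            {
                "sample": rare_mae["sample"],
                "strategy": "mae",
                "feature": rare_mae["variant_id"],
                "effect": rare_mae["log2_alt_ref"],
                "padj": rare_mae["padj"],
                "detail": "alt_freq=" + rare_mae["alt_frequency"].round(3).astype(str),
            }
        ),
    ]
    nonempty = [f for f in cand_frames if len(f)]
    candidates = (
        pd.concat(nonempty, ignore_index=True) if nonempty else cand_frames[0]
    )
    for label, members in (gene_lists or {}).items():
        candidates[f"in_{label}"] = candidates["feature"].isin(set(members))

    samples = [str(s) for s in counts.columns] if patient is None else [str(patient)]
    per_sample = pd.DataFrame(index=pd.Index(samples, name="sample"))
    per_sample["expression"] = (
        expr_out.groupby("sample").size().reindex(samples).fillna(0).astype(int)
    )
    per_sample["splicing"] = (
        spl_calls.groupby("sample").size().reindex(samples).fillna(0).astype(int)
        if len(spl_calls)
        else 0
    )
    per_sample["rare_mae"] = (
        rare_mae.groupby("sample").size().reindex(samples).fillna(0).astype(int)
        if len(rare_mae)
        else 0
    )

    summary = {
        "n_samples": len(samples),
        "median": {k: float(per_sample[k].median()) for k in per_sample.columns},
        "p90": {
            k: float(np.percentile(per_sample[k], 90)) for k in per_sample.columns
        },
        "weak_fraction": weak_fraction if weak_fraction is None or np.isfinite(weak_fraction) else None,
        "weak_fold": weak_fold if weak_fold is None or np.isfinite(weak_fold) else None,
        "thresholds": asdict(t),
    }
    note("done")

    report = OutlierReport(
        expression=expr,
        splicing=spl_calls,
        mae=mae_table,
        site_classes=site_classes,
        candidates=candidates,
        per_sample=per_sample,
        summary=summary,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        expr.to_csv(out / "expression.tsv", sep="\t", index=False)
        spl = spl_calls.copy()
        if len(spl):
            spl["event_sites"] = spl["event_sites"].map(",".join)
        spl.to_csv(out / "splicing.tsv", sep="\t", index=False)
        mae_table.to_csv(out / "mae.tsv", sep="\t", index=False)
        site_classes.to_csv(out / "site_classes.tsv", sep="\t", index=False)
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        per_sample.to_csv(out / "per_sample.tsv", sep="\t")
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return report
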