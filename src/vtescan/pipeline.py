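"""End-to-end orchestration: simulate -> discover -> associate -> report.

The pipeline mirrors the two-part study design: a family discovery
cascade that must return the planted causal variant, followed by exact
case-control and case-versus-background association at that variant,
with covariate comparisons, a logistic confounding check, a sex-split
binomial test among case carriers, and subcohort homogeneity.

Reports are JSON (machine) plus a rendered text summary (human).  The
single timestamp lives in one provenance field so that reports from
identical configs are otherwise byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from . import stats
from .filters import CascadeConfig, run_cascade
from .io import MISSING
from .simulate import (
    CohortDataset,
    SimulationConfig,
    generate_case_control_cohort,
    generate_family_exomes,
    write_cohort_dataset,
    write_family_dataset,
)
from .stats import AlleleCount, TwoByTwoTable, allele_counts, build_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "associate_cohort"]


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = SimulationConfig()
    cascade: CascadeConfig = CascadeConfig()
    run_discovery: bool = True
    run_association: bool = True
    run_covariates: bool = True
    run_homogeneity: bool = True
    p_method: str = "minlike"
    ci_method: str = "minlike"
    level: float = 0.95
    outdir: str | Path | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["candidate_regions"] = [
            dataclasses.asdict(r) for r in self.simulation.candidate_regions
        ]
        d["outdir"] = str(self.outdir) if self.outdir else None
        for key in ("extra_truth_populations", "case_subcohort_fracs",
                    "control_subcohort_fracs", "covariate_means_cases",
                    "covariate_means_controls", "covariate_sds"):
            d["simulation"][key] = dict(d["simulation"][key])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, float) and math.isinf(x):
        return "inf" if x > 0 else "-inf"
    if isinstance(x, float) and math.isnan(x):
        return "nan"
    return x


def _clean(obj):
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonable(obj.item())
    return _jsonable(obj)


def associate_cohort(
    cohort: CohortDataset,
    background: AlleleCount | None,
    p_method: str = "minlike",
    ci_method: str = "minlike",
    level: float = 0.95,
) -> dict:
    """Exact association of the tested variant: case-control, and
    case-versus-background when a background count is supplied."""
    case_ac = allele_counts(cohort.case_calls)
    ctrl_ac = allele_counts(cohort.control_calls)
    out = {
        "case_alleles": {"minor": case_ac.minor, "total": case_ac.total,
                         "maf_pct": round(100 * case_ac.frequency, 2)},
        "control_alleles": {"minor": ctrl_ac.minor, "total": ctrl_ac.total,
                            "maf_pct": round(100 * ctrl_ac.frequency, 2)},
        "case_control": stats.associate(
            build_table(case_ac, ctrl_ac), p_method, ci_method, level
        ).to_dict(),
    }
    if background is not None:
        out["background_alleles"] = {
            "minor": background.minor, "total": background.total,
            "maf_pct": round(100 * background.frequency, 2),
        }
        out["case_background"] = stats.associate(
            build_table(case_ac, background), p_method, ci_method, level
        ).to_dict()
    return out


def _sex_binomial(cohort: CohortDataset) -> dict | None:
    """Binomial test: are female case carriers over-represented relative to
    the female fraction among cases?"""
    cov = cohort.covariates
    is_case = (cov["status"] == "case").to_numpy()
    carrier = cohort.genotypes > 0
    case_carriers = is_case & carrier
    n = int(case_carriers.sum())
    if n == 0:
        return None
    female = (cov["sex"] == "F").to_numpy()
    k = int((case_carriers & female).sum())
    p0 = float(female[is_case].mean())
    if not (0.0 < p0 < 1.0):
        return None
    return {"female_carriers": k, "case_carriers": n, "p0_female_among_cases": round(p0, 4),
            "p_value": stats.binomial_two_sided(k, n, p0)}


def _homogeneity(cohort: CohortDataset) -> dict:
    tables: dict[str, TwoByTwoTable] = {}
    cov = cohort.covariates
    for name in sorted(cov["subcohort"].unique()):
        mask = (cov["subcohort"] == name).to_numpy()
        case_mask = mask & (cov["status"] == "case").to_numpy()
        ctrl_mask = mask & (cov["status"] == "control").to_numpy()
        tables[name] = build_table(
            allele_counts(cohort.genotypes[case_mask]),
            allele_counts(cohort.genotypes[ctrl_mask]),
        )
    pairwise = stats.subcohort_homogeneity(tables)
    return {
        arm: {f"{i}|{j}": p for (i, j), p in pairs.items()}
        for arm, pairs in pairwise.items()
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage and return the report dict.

    With ``config.outdir`` set, all artifacts (family VCF/BED/TSVs,
    cohort VCF/TSV, report.json, report.txt) are written under it.
    """
    report: dict = {
        "provenance": {
            "tool": "vtescan",
            "version": __version__,
            "seed": config.simulation.seed,
            "config_hash": config.config_hash(),
            "generated_at": datetime.now(timezone.utc).isoformat(),
        }
    }
    outdir = Path(config.outdir) if config.outdir else None

    if config.run_discovery:
        logger.info("[discover] simulating family exome and running cascade")
        family = generate_family_exomes(config.simulation)
        if outdir:
            write_family_dataset(family, outdir / "family")
        candidates, trace = run_cascade(family, config.cascade)
        report["discovery"] = {
            "truth_variant": family.truth,
            "candidates": sorted(candidates.keys),
            "recovered_truth_only": candidates.keys == {family.truth},
            "deleterious_flags": {
                c.variant.key: {
                    "sift": c.annotation.sift_category if c.annotation else "missing",
                    "polyphen": c.annotation.polyphen_category if c.annotation else "missing",
                    "deleterious": c.deleterious,
                }
                for c in candidates.candidates
            },
            "trace": trace.to_dict(),
        }

    if config.run_association or config.run_covariates or config.run_homogeneity:
        logger.info("[associate] simulating case-control cohort")
        cohort = generate_case_control_cohort(config.simulation)
        if outdir:
            write_cohort_dataset(cohort, outdir / "cohort")

        if config.run_association:
            background = AlleleCount(
                minor=config.simulation.background_carriers,
                total=2 * config.simulation.background_n,
            )
            report["association"] = associate_cohort(
                cohort, background, config.p_method, config.ci_method, config.level
            )
            sexb = _sex_binomial(cohort)
            if sexb is not None:
                report["association"]["sex_binomial_cases"] = sexb

        if config.run_covariates:
            cov = cohort.covariates
            cases = cov[cov["status"] == "case"]
            controls = cov[cov["status"] == "control"]
            report["covariates"] = [
                dataclasses.asdict(c)
                for c in stats.compare_covariates(cases, controls)
            ]
            fit = stats.logistic_fit(
                cov[["height", "weight"]].assign(carrier=(cohort.genotypes > 0).astype(float)),
                (cov["status"] == "case").astype(int).to_numpy(),
            )
            report["logistic_model"] = {
                "predictors": fit.names,
                "coef": list(fit.coef),
                "se": list(fit.se),
                "z": list(fit.z),
                "p": list(fit.p),
                "converged": fit.converged,
                "iterations": fit.iterations,
                "n_used": fit.n_used,
                "n_excluded": fit.n_excluded,
                "separated": fit.separated,
            }

        if config.run_homogeneity:
            report["homogeneity"] = _homogeneity(cohort)

    report = _clean(report)
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        (outdir / "report.txt").write_text(render_text_report(report))
    return report


def _fmt(x, spec: str = ".2f") -> str:
    """Format a report number that may have been serialized as 'inf'/'nan'."""
    if isinstance(x, str):
        return x
    return format(x, spec)


def render_text_report(report: dict) -> str:
    lines = ["vtescan pipeline report", "=" * 24]
    prov = report.get("provenance", {})
    lines.append(f"seed={prov.get('seed')} config={prov.get('config_hash')} "
                 f"version={prov.get('version')}")
    if "discovery" in report:
        d = report["discovery"]
        lines.append("")
        lines.append("Family discovery cascade:")
        for s in d["trace"]["stages"]:
            lines.append(f"  {s['name']:<22} {s['n_in']:>5} -> {s['n_out']}")
        lines.append(f"  candidates: {', '.join(d['candidates']) or '(none)'}")
        lines.append(f"  planted variant recovered alone: {d['recovered_truth_only']}")
    if "association" in report:
        a = report["association"]
        lines.append("")
        lines.append("Association (allele counts):")
        lines.append(f"  cases    MAF {a['case_alleles']['maf_pct']}% "
                     f"({a['case_alleles']['minor']}/{a['case_alleles']['total']})")
        lines.append(f"  controls MAF {a['control_alleles']['maf_pct']}% "
                     f"({a['control_alleles']['minor']}/{a['control_alleles']['total']})")
        for key, label in (("case_control", "case vs control"),
                           ("case_background", "case vs background")):
            if key in a:
                r = a[key]
                lines.append(
                    f"  {label}: p={_fmt(r['p_value'], '.4g')} ({r['p_method']}), "
                    f"OR={_fmt(r['or_sample'])}, "
                    f"{int(r['ci_level'] * 100)}% CI ({r['ci_method']}) = "
                    f"[{_fmt(r['ci_lower'])}, {_fmt(r['ci_upper'])}]"
                )
    if "logistic_model" in report:
        m = report["logistic_model"]
        lines.append("")
        lines.append(f"Logistic model (n={m['n_used']}, excluded={m['n_excluded']}, "
                     f"converged={m['converged']}):")
        for name, b, se, p in zip(m["predictors"], m["coef"], m["se"], m["p"]):
            lines.append(f"  {name:<10} beta={_fmt(b, '+.4f')} se={_fmt(se, '.4f')} "
                         f"p={_fmt(p, '.3g')}")
    if "homogeneity" in report:
        lines.append("")
        lines.append("Subcohort homogeneity (pairwise exact p):")
        for arm, pairs in report["homogeneity"].items():
            for pair, p in pairs.items():
                lines.append(f"  {arm:<8} {pair}: p={_fmt(p, '.3g')}")
    return "\n".join(lines) + "\n"
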