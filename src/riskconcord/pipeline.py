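"""End-to-end orchestration: simulate -> score -> eligibility -> agreement ->
consensus, with seeded determinism and machine-readable outputs.

A run directory contains: ``cohort.csv`` (if simulated), ``risks.csv``,
``eligibility.csv``, ``metrics.csv``, ``consensus.csv``, ``report.json`` and
``manifest.json``.  Identical seed + configs give byte-identical CSVs and
report; the manifest carries the run fingerprint (a hash over the cohort
configuration, the active threshold policies, the coefficient registries,
the seed and the package version) plus a wall-clock timestamp that is
deliberately excluded from the fingerprint.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import metric_matrix, pairwise_panel, panel_to_frame
from .cohort import cohort_to_frame, read_cohort
from .consensus import consensus_curve, curve_features
from .eligibility import (
    classify_eligibility,
    eligibility_rates,
    load_threshold_policies,
    policy_fingerprint,
)
from .engines import MODEL_ORDER, ModelId, score_all
from .engines.base import load_registry
from .synthetic import config_from_yaml, default_config_from_table1, generate_cohort

log = logging.getLogger("riskconcord")

__all__ = ["run_pipeline", "render_report", "validate_report"]

STRATA = ("overall", "female", "male")


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _registry_hash() -> str:
    parts = []
    for model in ModelId:
        parts.append(json.dumps(load_registry(model), sort_keys=True, default=str))
    return _sha256("|".join(parts))


def _write_csv(df: pd.DataFrame, path: Path, fingerprint: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {fingerprint}\n")
        df.to_csv(fh, index=index, float_format="%.10g", lineterminator="\n")


def run_pipeline(
    out_dir,
    *,
    seed: int = 0,
    n: int = 5000,
    cohort_path=None,
    cohort_config=None,
    policy_config=None,
    stratify_sex: bool = True,
) -> Path:
    """Run the full pipeline into ``out_dir`` and return that directory.

    The cohort is either loaded from ``cohort_path`` or simulated (``n``
    records, ``seed``); ``cohort_config``/``policy_config`` are YAML paths or
    parsed structures overriding the shipped defaults.  Any stage failure
    aborts with a stage-named diagnostic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    stage = "configure"
    try:
        policies = load_threshold_policies(policy_config)
        if cohort_path is None:
            if cohort_config is None:
                sim_config = default_config_from_table1(n=n, seed=seed)
            elif isinstance(cohort_config, (str, Path)):
                sim_config = dataclasses.replace(
                    config_from_yaml(cohort_config), n=n, seed=seed
                )
            else:
                sim_config = dataclasses.replace(cohort_config, n=n, seed=seed)
            cohort_cfg_doc = dataclasses.asdict(sim_config)
            cohort_cfg_doc["rank_corr"] = sorted(
                (list(k), v) for k, v in sim_config.rank_corr.items()
            )
            cohort_hash = _sha256(json.dumps(cohort_cfg_doc, sort_keys=True, default=str))
        else:
            sim_config = None
            cohort_hash = None

        stage = "simulate" if cohort_path is None else "load_cohort"
        if cohort_path is None:
            cohort = generate_cohort(sim_config)
        else:
            cohort = read_cohort(cohort_path)
            cohort_hash = _sha256(Path(cohort_path).read_text())
        log.info("%s: %d records (%.2fs)", stage, len(cohort), time.perf_counter() - t0)
        fingerprint = _sha256(
            json.dumps(
                {
                    "cohort": cohort_hash,
                    "policies": policy_fingerprint(policies),
                    "registries": _registry_hash(),
                    "seed": seed,
                    "version": __version__,
                },
                sort_keys=True,
            )
        )
        if cohort_path is None:
            _write_csv(cohort_to_frame(cohort), out / "cohort.csv",
                       fingerprint, index=False)

        stage = "score"
        risks = score_all(cohort)
        _write_csv(risks.risks, out / "risks.csv", fingerprint, index=True)

        stage = "eligibility"
        ages = pd.Series([r.age for r in cohort], index=risks.risks.index)
        matrix = classify_eligibility(risks, policies, ages)
        elig_out = matrix.decisions.astype(int).copy()
        elig_out.insert(0, "sex", matrix.sex)
        _write_csv(elig_out, out / "eligibility.csv", fingerprint, index=True)

        stage = "agreement"
        strata = list(STRATA if stratify_sex else ("overall",))
        for stratum in list(strata):
            if stratum != "overall" and (matrix.sex == stratum).sum() < 2:
                log.warning("skipping stratum %r: fewer than 2 participants", stratum)
                strata.remove(stratum)
        metric_frames = []
        panels_by_stratum = {}
        for stratum in strata:
            panels, summary = pairwise_panel(matrix.decisions, matrix.sex, stratum)
            panels_by_stratum[stratum] = (panels, summary)
            metric_frames.append(panel_to_frame(panels, stratum))
        _write_csv(pd.concat(metric_frames, ignore_index=True),
                   out / "metrics.csv", fingerprint, index=False)

        stage = "consensus"
        curves = {s: consensus_curve(matrix.decisions, matrix.sex, s) for s in strata}
        _write_csv(pd.concat([c.as_frame() for c in curves.values()], ignore_index=True),
                   out / "consensus.csv", fingerprint, index=False)

        stage = "report"
        report = render_report(
            matrix=matrix, risks=risks, policies=policies,
            panels_by_stratum=panels_by_stratum, curves=curves,
            fingerprint=fingerprint,
        )
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

        manifest = {
            "fingerprint": fingerprint,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
            "seed": seed,
            "package_version": __version__,
            "config_hashes": {
                "cohort": cohort_hash,
                "policies": policy_fingerprint(policies),
                "coefficient_registries": _registry_hash(),
            },
            "row_counts": {
                "cohort": len(cohort),
                "risks": len(risks.risks),
                "eligibility": len(matrix.decisions),
                "metric_pairs_per_stratum": len(MODEL_ORDER) * (len(MODEL_ORDER) - 1) // 2,
            },
            "files": sorted(p.name for p in out.iterdir() if p.suffix in (".csv", ".json")),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    log.info("pipeline complete in %.2fs", time.perf_counter() - t0)
    return out


def render_report(*, matrix, risks, policies, panels_by_stratum, curves, fingerprint) -> dict:
    """Assemble the machine-readable run report (validated against the
    shipped schema by :func:`validate_report`)."""
    rates = eligibility_rates(matrix, "both" if set(curves) != {"overall"} else "overall")
    report = {
        "manifest": fingerprint,
        "policies": [policies[m].describe() for m in ModelId],
        "eligibility": rates.to_dict("records"),
        "agreement": {},
        "consensus": {},
        "scoring_failures": len(risks.failures),
    }
    def _records(df: pd.DataFrame) -> list[dict]:
        # flagged-undefined metrics serialize as JSON null, never NaN
        return df.astype(object).where(df.notna(), None).to_dict("records")

    for stratum, (panels, summary) in panels_by_stratum.items():
        report["agreement"][stratum] = {
            "pairs": _records(panel_to_frame(panels, stratum)),
            "summary": _records(summary.reset_index()),
        }
    feats = curve_features(
        curves["overall"], curves.get("female"), curves.get("male")
    )
    for stratum, curve in curves.items():
        report["consensus"][stratum] = {
            "coverage_percent": {str(k): v for k, v in curve.coverage.items()},
            "counts": {str(k): v for k, v in curve.counts.items()},
            "denominator": curve.denominator,
        }
    report["consensus"]["features"] = {
        "steepest_drop": feats.steepest_drop,
        "steepest_drop_interval": list(feats.steepest_drop_interval),
        "half_coverage_k": feats.half_coverage_k,
        "max_sex_gap_k": feats.max_sex_gap_k,
        "max_sex_gap": feats.max_sex_gap,
    }
    validate_report(report)
    return report


def validate_report(report: dict) -> None:
    """Enforce the shipped report schema (required keys and types)."""
    schema = json.loads(
        resources.files("riskconcord.data").joinpath("report_schema.json").read_text()
    )
    problems = []
    for key, typ in schema["required"].items():
        if key not in report:
            problems.append(f"missing key '{key}'")
        elif type(report[key]).__name__ not in typ:
            problems.append(f"key '{key}' has type {type(report[key]).__name__}, wanted {typ}")
    for block in ("overall",):
        if "agreement" in report and block not in report["agreement"]:
            problems.append(f"agreement lacks '{block}' stratum")
        if "consensus" in report and block not in report["consensus"]:
            problems.append(f"consensus lacks '{block}' stratum")
    if problems:
        raise ValueError("report violates schema: " + "; ".join(problems))


def metric_heatmap(panels, metric: str, models=MODEL_ORDER, ax=None):
    """Convenience heatmap of one agreement metric (requires matplotlib;
    the matrix CSVs are the contract, plotting is optional)."""
    import matplotlib.pyplot as plt  # deferred: optional dependency

    m = metric_matrix(panels, metric, list(models))
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(m.to_numpy(), vmin=-0.25, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(len(models)), models, rotation=45, ha="right")
    ax.set_yticks(range(len(models)), models)
    ax.figure.colorbar(im, ax=ax, label=metric)
    ax.set_title(f"pairwise {metric}")
    return ax
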