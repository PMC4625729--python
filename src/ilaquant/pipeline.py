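"""End-to-end orchestration: phantom validation, cohort analysis, and the
full synthetic reproduction (phantoms -> densitometry; cohort -> agreement
-> association), with deterministic, provenance-stamped text outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import association as assoc
from .cohort import CohortSimSpec, read_cohort, simulate_cohort, write_cohort
from .densitometry import run_densitometry, segment_lungs
from .phantom import PhantomSpec, generate_phantom

log = logging.getLogger("ilaquant")

MODES = ("phantom_validate", "cohort_analysis", "full_synthetic")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    mode: str = "full_synthetic"
    seed: int = 0
    output_dir: str = "ilaquant_out"
    cohort_path: str | None = None  # for cohort_analysis
    n_phantoms: int = 5
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSimSpec = field(default_factory=CohortSimSpec)
    thresholds: tuple[float, ...] = (10.0,)
    percentile: float | None = 95.0
    policies: tuple[str, ...] = ("exclude", "as_control")

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "cohort_analysis" and not self.cohort_path:
            raise ConfigError("cohort_analysis mode requires cohort_path")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = self.phantom.to_dict()
        d["cohort"] = self.cohort.to_dict()
        d["thresholds"] = list(self.thresholds)
        d["policies"] = list(self.policies)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "phantom" in kwargs:
            kwargs["phantom"] = PhantomSpec.from_dict(kwargs["phantom"])
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortSimSpec.from_dict(kwargs["cohort"])
        for k in ("thresholds", "policies"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("cohort_path", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("phantom_densitometry")
def phantom_densitometry_table(config: RunConfig) -> pd.DataFrame:
    """Generate phantoms and measure them with both truth and segmented
    masks, reporting measured vs true fractions per scan."""
    from .densitometry import LungMask

    rows = []
    for i in range(config.n_phantoms):
        spec = dataclasses.replace(config.phantom, seed=config.seed + i)
        vol, truth = generate_phantom(spec)
        truth_mask = LungMask(mask=truth.lung_mask, provenance="ground_truth")
        r_truth = run_densitometry(vol, truth_mask)
        seg = segment_lungs(vol)
        r_seg = run_densitometry(vol, seg)
        inter = (seg.mask & truth.lung_mask).sum()
        dice = 2.0 * inter / (seg.mask.sum() + truth.lung_mask.sum())
        rows.append(
            {
                "phantom_seed": spec.seed,
                "true_haa_pct": 100 * truth.true_haa_fraction,
                "true_emph_pct": 100 * truth.true_emph_fraction,
                "true_tlc_l": truth.true_lung_volume_l,
                "haa_pct_truth_mask": r_truth.haa_pct,
                "emph_pct_truth_mask": r_truth.emph_pct,
                "tlc_l_truth_mask": r_truth.tlc_l,
                "haa_pct_segmented": r_seg.haa_pct,
                "emph_pct_segmented": r_seg.emph_pct,
                "tlc_l_segmented": r_seg.tlc_l,
                "mask_dice": float(dice),
            }
        )
    return pd.DataFrame(rows)


@_stage("agreement")
def agreement_report(cohort: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Table-2-style agreement panel across thresholds and policies."""
    thresholds = [("fixed", float(t)) for t in config.thresholds]
    if config.percentile is not None:
        thr = agr.percentile_threshold(cohort["haa_pct"], config.percentile)
        thresholds.append((f"p{config.percentile:g}", thr))
    rows = []
    for label, thr in thresholds:
        for policy in config.policies:
            t = agr.build_contingency(cohort, thr, policy)
            s = agr.diagnostic_panel(t, threshold_used=thr)
            rows.append(
                {
                    "threshold_label": label,
                    "threshold_pct": thr,
                    "policy": policy,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "n_indeterminate_absorbed": t.n_indeterminate_absorbed,
                    "kappa": s.kappa,
                    "kappa_p": s.kappa_p,
                    "sensitivity": s.sensitivity,
                    "specificity": s.specificity,
                    "ppv": s.ppv,
                    "npv": s.npv,
                }
            )
    return pd.DataFrame(rows)


@_stage("association")
def association_report(cohort: pd.DataFrame) -> pd.DataFrame:
    results = [
        ("ila_or_exclude", assoc.fit_ila_logistic(cohort, indeterminate_policy="exclude")),
        ("ila_or_as_control", assoc.fit_ila_logistic(cohort, indeterminate_policy="as_control")),
        ("tlc_slope_all", assoc.fit_tlc_linear(cohort, subset="all")),
    ]
    if (cohort["visual_status"] == "ila").any():
        results.append(("tlc_slope_ila_only", assoc.fit_tlc_linear(cohort, subset="ila_only")))
    try:
        strata, p_int = assoc.stratified_effects(cohort, "emph_pct@5")
        results += [("ila_or_by_emphysema", r) for r in strata]
    except (assoc.StratumError, assoc.SeparationError) as exc:
        log.warning("emphysema-stratified fit skipped: %s", exc)
        p_int = np.nan
    if cohort["genotype"].nunique() > 1:
        results.append(("genotype_haa_continuous", assoc.genotype_association(cohort)))
    table = assoc.association_table(results)
    table.attrs["emphysema_interaction_p"] = p_int
    return table


@_stage("density_plot_data")
def haa_density_data(cohort: pd.DataFrame, bins=None) -> pd.DataFrame:
    """Per-group normalized HAA% histograms (density-plot data)."""
    if bins is None:
        bins = np.arange(0.0, 20.5, 0.5)
    out = {"bin_left": bins[:-1], "bin_right": bins[1:]}
    for group in ("no_ila", "indeterminate", "ila"):
        vals = cohort.loc[cohort["visual_status"] == group, "haa_pct"]
        if len(vals):
            dens, _ = np.histogram(vals, bins=bins, density=True)
        else:
            dens = np.full(len(bins) - 1, np.nan)
        out[f"density_{group}"] = dens
    return pd.DataFrame(out)


def run(config: RunConfig) -> dict:
    """Execute the configured mode; returns {artifact name: path}."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"# seed={config.seed} config_hash={config.config_hash()}\n"
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(stamp)
            df.to_csv(fh, sep="\t", index=False)
        written[name] = path
        log.info("wrote %s (%d rows)", path, len(df))

    if config.mode == "phantom_validate":
        emit("densitometry", phantom_densitometry_table(config))
    else:
        if config.mode == "full_synthetic":
            spec = dataclasses.replace(config.cohort, seed=config.seed)
            cohort = simulate_cohort(spec)
            write_cohort(cohort, outdir / "cohort.tsv")
            written["cohort"] = outdir / "cohort.tsv"
        else:
            cohort = read_cohort(config.cohort_path)
        agree = agreement_report(cohort, config)
        emit("agreement", agree)
        atab = association_report(cohort)
        emit("association", atab)
        emit("haa_density", haa_density_data(cohort))
        summary = outdir / "summary.txt"
        with open(summary, "w") as fh:
            fh.write(stamp)
            fh.write(format_agreement_summary(agree))
        written["summary"] = summary
    return written


def format_agreement_summary(agree: pd.DataFrame) -> str:
    """Plain-text agreement summary, one block per threshold/policy."""
    lines = []
    for _, r in agree.iterrows():
        lines.append(
            f"threshold {r['threshold_label']} ({r['threshold_pct']:.2f}%), "
            f"indeterminates {r['policy']}"
        )
        lines.append(
            f"  counts a={r['a']} b={r['b']} c={r['c']} d={r['d']} "
            f"(indeterminate absorbed: {r['n_indeterminate_absorbed']})"
        )
        kp = "NA" if pd.isna(r["kappa_p"]) else f"{r['kappa_p']:.4g}"
        lines.append(f"  kappa {r['kappa']:.2f} (p={kp})")
        panel = ", ".join(
            f"{k} {100 * r[k]:.0f}%"
            for k in ("sensitivity", "specificity", "ppv", "npv")
            if pd.notna(r[k])
        )
        lines.append(f"  {panel}")
    return "\n".join(lines) + "\n"
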