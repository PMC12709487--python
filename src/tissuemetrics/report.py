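"""Group comparison tables and the end-to-end analysis pipeline.

The study's deliverable is a control-vs-disease comparison of every
texture metric: pooled group means and standard deviations, their
absolute differences, and percentage differences relative to the control
group.  :func:`compare_groups` builds one such row;
:func:`run_full_analysis` drives the whole pipeline (simulate or load
images -> fractal maps -> transforms -> multifractal spectra -> IPR
maps) from a single configuration and emits the comparison table, the
distribution summaries and the sweep tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import boxcount, ipr, mfa, synth, transforms
from .image_io import GrayImage, binarize

__all__ = [
    "GroupComparison",
    "RunConfig",
    "AnalysisBundle",
    "compare_groups",
    "comparison_table",
    "run_full_analysis",
]


@dataclass(frozen=True)
class GroupComparison:
    """One row of the comparison table for a single metric.

    Differences are disease minus control; percentage differences are
    relative to the control value (NaN when the control value is zero).
    Standard deviations use the population convention (divide by n) over
    the pooled per-sub-box values.
    """

    metric: str
    control_mean: float
    disease_mean: float
    mean_difference: float
    mean_pct_difference: float
    control_std: float
    disease_std: float
    std_difference: float
    std_pct_difference: float

    def as_row(self) -> dict:
        return asdict(self)


def _pct(difference: float, reference: float) -> float:
    return 100.0 * difference / reference if reference != 0 else float("nan")


def compare_groups(control: np.ndarray, disease: np.ndarray,
                   metric: str = "", ddof: int = 0) -> GroupComparison:
    """Means, stds and relative differences of two pooled value sets."""
    c = np.asarray(control, dtype=float)
    d = np.asarray(disease, dtype=float)
    c, d = c[np.isfinite(c)], d[np.isfinite(d)]
    if c.size == 0 or d.size == 0:
        raise ValueError("both groups must contain at least one finite value")
    cm, dm = float(c.mean()), float(d.mean())
    cs = float(c.std(ddof=ddof)) if c.size > ddof else float("nan")
    ds = float(d.std(ddof=ddof)) if d.size > ddof else float("nan")
    return GroupComparison(
        metric=metric,
        control_mean=cm, disease_mean=dm,
        mean_difference=dm - cm, mean_pct_difference=_pct(dm - cm, cm),
        control_std=cs, disease_std=ds,
        std_difference=ds - cs, std_pct_difference=_pct(ds - cs, cs),
    )


def comparison_table(rows: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in rows])


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs.

    Either a simulation (n_images/side/presets via ``cohort_spec``) or a
    pre-loaded mapping of group name -> images via ``images``.
    """

    cohort_spec: synth.CohortSpec | None = None
    images: Mapping[str, Sequence[GrayImage]] | None = None
    block_side: int = 32
    threshold_fraction: float = 0.65
    invert: bool = False
    n_bins: int = 70
    poly_degree: int = 8
    epsilon_guard: float = 1e-6
    ipr_block_side: int = 32
    hopping: float = 1.0
    mfa_scales: tuple[int, ...] | None = None
    q_min: float = -10.0
    q_max: float = 10.0
    q_step: float = 0.5
    run_mfa: bool = True
    run_ipr: bool = True
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.cohort_spec is None) == (self.images is None):
            raise ValueError("provide exactly one of cohort_spec or images")
        if not 0.0 <= self.threshold_fraction <= 1.0:
            raise ValueError("threshold_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class AnalysisBundle:
    """All outputs of one pipeline run."""

    comparisons: pd.DataFrame          # Table-1-shaped metric comparisons
    df_values: dict[str, np.ndarray]   # pooled sub-box Df per group
    distributions: dict                # metric -> group -> DistributionSummary
    spectra: dict                      # group -> list of MultifractalSpectrum
    spectrum_widths: dict              # group -> per-image widths
    ipr_results: dict                  # group -> list of IPRResult
    ipr_stats: ipr.GroupIPRStats | None
    manifest: pd.DataFrame | None
    config: RunConfig


def _metric_maps(df_vals: dict[str, np.ndarray], guard: float
                 ) -> dict[str, dict[str, np.ndarray]]:
    """Df, lnDf, lnDtf per group, with df_max pooled over both groups."""
    pooled = np.concatenate(list(df_vals.values()))
    params = transforms.TransformParams.from_values(pooled, epsilon_guard=guard)
    out: dict[str, dict[str, np.ndarray]] = {"Df": {}, "lnDf": {}, "lnDtf": {}}
    for g, v in df_vals.items():
        out["Df"][g] = v
        out["lnDf"][g] = transforms.log_transform(v)
        out["lnDtf"][g] = transforms.log_transform(
            transforms.functional_transform(v, params))
    return out


def run_full_analysis(cfg: RunConfig) -> AnalysisBundle:
    """Drive the full pipeline and collect every table.

    Deterministic for a fixed config: simulation seeds live in the
    cohort spec and every analysis stage is seed-free.
    """
    manifest = None
    if cfg.cohort_spec is not None:
        cohorts = synth.make_cohorts(cfg.cohort_spec)
        groups = cohorts.groups
        manifest = cohorts.manifest
    else:
        groups = {k: list(v) for k, v in cfg.images.items()}

    # --- sub-box fractal dimensions and their transforms -----------------
    df_vals = {
        g: boxcount.pooled_df_values(imgs, cfg.block_side,
                                     cfg.threshold_fraction, cfg.invert)
        for g, imgs in groups.items()
    }
    metric_maps = _metric_maps(df_vals, cfg.epsilon_guard)

    rows = []
    distributions: dict[str, dict] = {}
    for metric, per_group in metric_maps.items():
        distributions[metric] = {}
        for g, vals in per_group.items():
            finite = vals[np.isfinite(vals)]
            if finite.size >= 2:
                distributions[metric][g] = transforms.summarize_distribution(
                    finite, cfg.n_bins, cfg.poly_degree)
        if "control" in per_group and "disease" in per_group:
            rows.append(compare_groups(per_group["control"],
                                       per_group["disease"], metric))

    # --- multifractal spectra -------------------------------------------
    spectra: dict[str, list] = {}
    widths: dict[str, np.ndarray] = {}
    if cfg.run_mfa:
        q_grid = mfa.default_q_grid(cfg.q_min, cfg.q_max, cfg.q_step)
        for g, imgs in groups.items():
            side = imgs[0].pixels.shape[0]
            scales = (list(cfg.mfa_scales) if cfg.mfa_scales
                      else mfa.default_mfa_scales(side))
            sp = [mfa.spectrum(img, q_grid, scales) for img in imgs]
            spectra[g] = sp
            widths[g] = np.array(
                [mfa.spectrum_metrics(s).width for s in sp])
        if "control" in widths and "disease" in widths:
            rows.append(compare_groups(widths["control"], widths["disease"],
                                       "f_alpha_width"))

    # --- IPR --------------------------------------------------------------
    ipr_results: dict[str, list] = {}
    ipr_stats = None
    if cfg.run_ipr:
        for g, imgs in groups.items():
            ipr_results[g] = [ipr.ipr_map(img, cfg.ipr_block_side, cfg.hopping)
                              for img in imgs]
        if "control" in ipr_results and "disease" in ipr_results:
            ipr_stats = ipr.group_ipr_stats(ipr_results)
            rows.append(compare_groups(
                np.concatenate([r.defined for r in ipr_results["control"]]),
                np.concatenate([r.defined for r in ipr_results["disease"]]),
                "IPR"))

    bundle = AnalysisBundle(
        comparisons=comparison_table(rows), df_values=df_vals,
        distributions=distributions, spectra=spectra, spectrum_widths=widths,
        ipr_results=ipr_results, ipr_stats=ipr_stats,
        manifest=manifest, config=cfg,
    )
    if cfg.output_dir is not None:
        _write_bundle(bundle, Path(cfg.output_dir))
    return bundle


def _write_bundle(bundle: AnalysisBundle, outdir: Path) -> None:
    """CSV/JSON export of the pipeline outputs."""
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.comparisons.to_csv(outdir / "comparisons.csv", index=False)
    if bundle.manifest is not None:
        bundle.manifest.to_csv(outdir / "manifest.csv", index=False)
    for g, vals in bundle.df_values.items():
        pd.DataFrame({"df": vals}).to_csv(outdir / f"df_values_{g}.csv",
                                          index=False)
    if bundle.spectra:
        rows = []
        for g, sps in bundle.spectra.items():
            for i, s in enumerate(sps):
                for q, a, f, t in zip(s.q_values, s.alpha, s.f_alpha, s.tau):
                    rows.append({"group": g, "image": i, "q": q,
                                 "alpha": a, "f_alpha": f, "tau": t})
        pd.DataFrame(rows).to_csv(outdir / "spectra.csv", index=False)
    if bundle.ipr_stats is not None:
        payload = {
            "table": bundle.ipr_stats.table.to_dict(orient="records"),
            "mean_pct_difference": bundle.ipr_stats.mean_pct_difference,
            "std_pct_difference": bundle.ipr_stats.std_pct_difference,
        }
        (outdir / "ipr_stats.json").write_text(json.dumps(payload, indent=2))
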