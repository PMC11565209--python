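"""End-to-end trait-extraction pipeline: simulate/load → fit → traits → stats.

The pipeline is a pure function of its inputs and configuration: per-plant
trait tables (QY, A_sat, g_ssat, τ_ai, τ_i, W_i at both light levels, SD and
anatomical g_smax), per-accession summaries with Tukey compact-letter groups
per trait, a correlation matrix across accession means, and a manifest
recording the configuration hash and seed so runs are reproducible
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import Constants, GasxSeries, read_anatomy_table, read_gasx_table
from .group_stats import anova, pearson, tukey_hsd
from .induction_kinetics import fit_induction, split_step, steady_state_wi
from .light_response import fit_light_response, summarize_light_curve
from .stomatal_anatomy import gsmax_table
from .synthetic_data import (
    GeneratorConfig,
    PanelData,
    read_truths,
    sample_panel,
    simulate_panel,
    write_dataset,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "extract_traits", "recovery_report"]

log = logging.getLogger("gasxkit")

#: Traits summarised and tested at the accession level.
TRAIT_COLUMNS = [
    "QY", "Asat", "gssat", "Rd", "tau_ai", "tau_i", "Wi_low", "Wi_high",
    "SD_ab", "SD_ad", "gsmax_ab", "gsmax_ad", "gsmax_leaf",
]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration: either a directory of input tables or a simulate block."""

    input_dir: str | None = None
    simulate: GeneratorConfig | None = None
    seed: int = 0
    alpha: float = 0.05
    constants: Constants = field(default_factory=Constants)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir or simulate must be given")
        if not 0 < self.alpha <= 0.5:
            raise ValueError(f"alpha must be in (0, 0.5], got {self.alpha}")

    def digest(self) -> str:
        raw = {
            "input_dir": self.input_dir,
            "simulate": dataclasses.asdict(self.simulate) if self.simulate else None,
            "seed": self.seed,
            "alpha": self.alpha,
            "constants": dataclasses.asdict(self.constants),
        }
        return hashlib.sha256(json.dumps(raw, sort_keys=True).encode()).hexdigest()


@dataclass
class PipelineResult:
    traits: pd.DataFrame            # one row per plant
    accession_means: pd.DataFrame   # one row per accession
    letters: dict[str, pd.DataFrame]  # trait → (accession, mean, letter)
    anova_tables: dict[str, pd.DataFrame]
    correlations: pd.DataFrame      # long: trait_x, trait_y, r, p
    manifest: dict


class StageError(RuntimeError):
    """A pipeline stage failed for a specific plant."""

    def __init__(self, stage: str, plant_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for plant {plant_id!r}: {cause}")
        self.stage = stage
        self.plant_id = plant_id
        self.cause = cause


def _load_inputs(input_dir: str) -> tuple[list[GasxSeries], list[GasxSeries], list]:
    root = Path(input_dir)
    light, step = [], []
    for path in sorted((root / "gasx" / "light").glob("*.csv")):
        light.extend(read_gasx_table(path))
    for path in sorted((root / "gasx" / "step").glob("*.csv")):
        step.extend(read_gasx_table(path))
    anatomy_path = root / "anatomy.tsv"
    anatomy = read_anatomy_table(anatomy_path) if anatomy_path.exists() else []
    if not light and not step:
        raise FileNotFoundError(f"no gas-exchange tables found under {root}")
    return light, step, anatomy


def extract_traits(
    light: list[GasxSeries],
    step: list[GasxSeries],
    anatomy: list,
    constants: Constants = Constants(),
) -> pd.DataFrame:
    """Per-plant trait table from raw series; one row per plant.

    Any stage failure is re-raised as :class:`StageError` naming the stage
    and the offending plant.
    """
    rows: dict[str, dict] = {}

    def _row(series) -> dict:
        return rows.setdefault(
            series.plant_id, {"plant_id": series.plant_id, "accession": series.accession}
        )

    for series in light:
        row = _row(series)
        try:
            fit = fit_light_response(series)
            summary = summarize_light_curve(series, fit)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise StageError("light_response", series.plant_id, exc) from exc
        row.update(
            QY=summary.QY, Asat=summary.Asat, gssat=summary.gssat,
            Rd=fit.Rd, Amax=fit.Amax, light_sse=fit.sse,
        )

    for series in step:
        row = _row(series)
        try:
            phases = split_step(series)
            fa = fit_induction(phases, "A")
            fg = fit_induction(phases, "gs")
            wi = steady_state_wi(phases)
        except Exception as exc:  # noqa: BLE001
            raise StageError("induction_kinetics", series.plant_id, exc) from exc
        row.update(
            tau_ai=fa.k, tau_i=fg.k, lam_a=fa.lam, lam_gs=fg.lam,
            A0=fa.y0, Af=fa.yf, gs0=fg.y0, gsf=fg.yf,
            Wi_low=wi.wi_low, Wi_high=wi.wi_high,
            no_response_A=fa.no_response, no_response_gs=fg.no_response,
        )

    if anatomy:
        try:
            anat = gsmax_table(anatomy, constants)
        except Exception as exc:  # noqa: BLE001
            raise StageError("stomatal_anatomy", "<panel>", exc) from exc
        for _, arow in anat.iterrows():
            row = rows.setdefault(
                arow["plant_id"],
                {"plant_id": arow["plant_id"], "accession": arow["accession"]},
            )
            for col in ("SD_mm2_ab", "SD_mm2_ad", "gsmax_ab", "gsmax_ad", "gsmax_leaf"):
                if col in arow:
                    row[col.replace("SD_mm2", "SD")] = arow[col]

    traits = pd.DataFrame(sorted(rows.values(), key=lambda r: r["plant_id"]))
    return traits.reset_index(drop=True)


def _accession_stats(traits: pd.DataFrame, alpha: float):
    """Per-trait accession means, one-way ANOVA, and Tukey letters."""
    means = traits.groupby("accession", sort=True).agg(
        n_plants=("plant_id", "nunique"),
        **{c: (c, "mean") for c in TRAIT_COLUMNS if c in traits.columns},
    ).reset_index()

    letters: dict[str, pd.DataFrame] = {}
    anova_tables: dict[str, pd.DataFrame] = {}
    counts = traits.groupby("accession")["plant_id"].nunique()
    enough_reps = (counts >= 2).all() and len(counts) >= 2
    for trait in TRAIT_COLUMNS:
        if trait not in traits.columns:
            continue
        sub = traits[["accession", trait]].dropna()
        if not enough_reps or sub.groupby("accession").size().min() < 2:
            continue
        try:
            anova_tables[trait] = anova(sub[trait].to_numpy(), sub["accession"].to_numpy())
            tk = tukey_hsd(sub[trait].to_numpy(), sub["accession"].to_numpy(), alpha=alpha)
        except ValueError:
            continue
        letters[trait] = pd.DataFrame(
            {
                "accession": tk.groups,
                "mean": [sub.loc[sub["accession"] == a, trait].mean() for a in tk.groups],
                "letters": [tk.letters[a] for a in tk.groups],
            }
        )
    return means, letters, anova_tables


def _correlations(means: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations across accession means."""
    present = [c for c in TRAIT_COLUMNS if c in means.columns]
    rows = []
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            sub = means[[a, b]].dropna()
            if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                continue
            r, p = pearson(sub[a].to_numpy(), sub[b].to_numpy())
            rows.append((a, b, r, p, len(sub)))
    return pd.DataFrame(rows, columns=["trait_x", "trait_y", "r", "p", "n"])


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full pipeline and (optionally) write tidy TSV outputs.

    Outputs are a pure function of (inputs, config): re-running with the same
    seed and configuration reproduces every table byte for byte.
    """
    truths_frame = None
    if config.simulate is not None:
        cfg = config.simulate
        log.info("simulating panel: %d accessions × %d plants (seed %d)",
                 cfg.n_accessions, cfg.n_plants, config.seed)
        truths = sample_panel(config=cfg, seed=config.seed)
        panel: PanelData = simulate_panel(truths, seed=config.seed, config=cfg)
        light, step, anatomy = panel.light, panel.step, panel.anatomy
        truths_frame = panel.truths_frame()
        if config.out_dir is not None:
            write_dataset(panel, Path(config.out_dir) / "dataset")
    else:
        log.info("loading inputs from %s", config.input_dir)
        light, step, anatomy = _load_inputs(config.input_dir)
        truths_path = Path(config.input_dir) / "truths.tsv"
        if truths_path.exists():
            truths_frame = read_truths(truths_path)

    log.info("extracting traits for %d plants",
             len({s.plant_id for s in light} | {s.plant_id for s in step}))
    traits = extract_traits(light, step, anatomy, config.constants)
    means, letters, anova_tables = _accession_stats(traits, config.alpha)
    correlations = _correlations(means)

    manifest = {
        "gasxkit_version": __version__,
        "config_sha256": config.digest(),
        "seed": config.seed,
        "alpha": config.alpha,
        "n_plants": int(traits["plant_id"].nunique()),
        "n_accessions": int(traits["accession"].nunique()),
        "plant_ids": sorted(traits["plant_id"].astype(str)),
    }
    result = PipelineResult(
        traits=traits, accession_means=means, letters=letters,
        anova_tables=anova_tables, correlations=correlations, manifest=manifest,
    )
    if config.out_dir is not None:
        _write_outputs(result, truths_frame, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, truths_frame, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.traits.to_csv(out / "traits.tsv", sep="\t", index=False)
    result.accession_means.to_csv(out / "accession_means.tsv", sep="\t", index=False)
    result.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    if result.letters:
        pd.concat(
            [df.assign(trait=trait) for trait, df in sorted(result.letters.items())],
            ignore_index=True,
        ).to_csv(out / "tukey_letters.tsv", sep="\t", index=False)
    if result.anova_tables:
        pd.concat(
            [tab.reset_index(names="term").assign(trait=trait)
             for trait, tab in sorted(result.anova_tables.items())],
            ignore_index=True,
        ).to_csv(out / "anova.tsv", sep="\t", index=False)
    if truths_frame is not None:
        rec = recovery_report(result.traits, truths_frame)
        rec.to_csv(out / "recovery.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


#: estimated trait column → truths column it estimates
RECOVERY_MAP = {
    "QY": "phi",
    "tau_ai": "k_A",
    "tau_i": "k_gs",
    "Rd": "Rd",
    "SD_ab": "SD_ab",
    "SD_ad": "SD_ad",
}


def recovery_report(traits: pd.DataFrame, truths: pd.DataFrame,
                    tolerances: dict[str, float] | None = None) -> pd.DataFrame:
    """Join estimates to generator truths and score relative errors.

    ``tolerances`` maps trait → acceptable relative error (defaults: 10% for
    kinetic time constants, 5% for QY, 15% for densities and Rd); the
    ``within_tol`` flag records whether each estimate met its tolerance.
    """
    tol = {"QY": 0.05, "tau_ai": 0.10, "tau_i": 0.10, "Rd": 0.15,
           "SD_ab": 0.15, "SD_ad": 0.15}
    if tolerances:
        tol.update(tolerances)
    # keep truth columns unambiguous: traits and truths share names like Rd
    truths = truths.rename(
        columns={c: f"{c}__truth" for c in truths.columns if c != "plant_id"}
    )
    merged = traits.merge(truths, on="plant_id")
    rows = []
    for trait, truth_name in RECOVERY_MAP.items():
        truth_col = f"{truth_name}__truth"
        if trait not in merged.columns or truth_col not in merged.columns:
            continue
        sub = merged[["plant_id", trait, truth_col]].dropna()
        for _, r in sub.iterrows():
            rel = abs(r[trait] - r[truth_col]) / abs(r[truth_col])
            rows.append(
                (r["plant_id"], trait, r[truth_col], r[trait], rel, rel <= tol[trait])
            )
    return pd.DataFrame(
        rows, columns=["plant_id", "trait", "truth", "estimate", "rel_err", "within_tol"]
    )
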