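"""End-to-end orchestration: cohort in, scoring table + evaluation out.

:class:`OrdinalScoreModel` is built from a cohort (a DataFrame plus outcome
declaration); :meth:`OrdinalScoreModel.fit` runs the whole workflow — stratified
split, imputation, quantile categorization, random-forest ranking, parsimony
sweep, variable selection, optional cutoff fine-tuning, integer score
derivation, lookup-table construction and test-set evaluation — and returns an
:class:`OrdinalScoreResults` carrying every intermediate artifact, a
``summary()`` table and prediction methods. :func:`run_pipeline` is the
config-file driven wrapper used by the command-line interface.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    CutoffScheme,
    DataSplit,
    OrdinalData,
    apply_cutoffs,
    compute_cutoffs,
    impute_median,
    split_data,
)
from .evaluation import (
    EvalReport,
    ParsimonyResult,
    calibration_report,
    evaluate,
    parsimony,
    plot_calibration,
    select_variables,
)
from .pom import POMResults
from .ranking import VariableRanking, rank_variables
from .scoring import LookupTable, ScoringTable, build_lookup, build_scoring_table, fine_tune

__all__ = ["RunConfig", "OrdinalScoreModel", "OrdinalScoreResults", "run_pipeline"]

DEFAULT_QUANTILE_RANKS = (0.05, 0.20, 0.80, 0.95)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    cohort: str | None = None
    output_dir: str = "ordiscore_output"
    outcome: str = "outcome"
    predictors: list[str] | None = None
    categorical: list[str] = field(default_factory=list)
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0
    n_trees: int = 100
    quantile_ranks: tuple[float, ...] = DEFAULT_QUANTILE_RANKS
    impute_reference: str = "train"
    fill_rules: dict[str, float] = field(default_factory=dict)
    max_k: int | None = None
    final_k: int | None = None
    include: list[str] = field(default_factory=list)
    exclude: list[str] = field(default_factory=list)
    cutoff_overrides: dict[str, list[float]] = field(default_factory=dict)
    rescale_target: int | None = 100
    lookup_bins: int | list[int] = 10
    n_boot: int = 100

    def __post_init__(self):
        if self.seed < 0 or self.n_boot < 1 or self.n_trees < 1:
            raise ValueError("seed, n_trees and n_boot must be positive integers")
        if self.impute_reference not in ("train", "validation"):
            raise ValueError("impute_reference must be 'train' or 'validation'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.ratios = tuple(cfg.ratios)
        cfg.quantile_ranks = tuple(cfg.quantile_ranks)
        return cfg

    def validate_columns(self, df: pd.DataFrame) -> None:
        cols = set(df.columns)
        wanted = [self.outcome] + (self.predictors or []) + self.categorical
        wanted += list(self.include) + list(self.exclude)
        wanted += list(self.fill_rules) + list(self.cutoff_overrides)
        missing = [c for c in wanted if c not in cols]
        if missing:
            raise ValueError(f"columns not found in cohort: {sorted(set(missing))}")


class OrdinalScoreModel:
    """The score-development workflow, bound to one cohort.

    Parameters
    ----------
    data : OrdinalData
        Full cohort (predictors + ordinal outcome coded 1..J).
    config : RunConfig, optional
        Workflow settings; keyword arguments to :meth:`fit` override it.
    """

    def __init__(self, data: OrdinalData, config: RunConfig | None = None):
        self.data = data
        self.config = config or RunConfig(outcome=data.outcome)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        predictors=None,
        categorical=(),
        config: RunConfig | None = None,
    ) -> "OrdinalScoreModel":
        data = OrdinalData(
            df, outcome, predictors=tuple(predictors or ()), categorical=tuple(categorical)
        )
        return cls(data, config=config)

    def fit(self, **overrides) -> "OrdinalScoreResults":
        """Run the full workflow and return the fitted results.

        Any :class:`RunConfig` field can be overridden by keyword. When
        ``final_k`` is not given, the model size with the highest validation
        mAUC is used (manual inspection of the parsimony plot is the intended
        workflow; the automatic choice keeps unattended runs reproducible).
        """
        cfg = RunConfig(**{**asdict(self.config), **overrides})
        data = self.data

        # Module 1a: stratified split
        split = split_data(data, cfg.ratios, cfg.seed)
        train, valid, test = (data.subset(i) for i in (split.train_idx, split.valid_idx, split.test_idx))

        # dataset-specific constant fills, then median imputation
        train, valid, test = (self._apply_fill(d, cfg.fill_rules) for d in (train, valid, test))
        ref = valid if (cfg.impute_reference == "validation" and valid.n) else train
        train, valid, test = (impute_median(ref, d) for d in (train, valid, test))

        # Module 2: quantile cutoffs from the training set
        scheme = compute_cutoffs(train, cfg.quantile_ranks)

        # Module 1b: random-forest ranking on the categorized training set
        cat_train = apply_cutoffs(train, scheme)
        ranking = rank_variables(cat_train, n_trees=cfg.n_trees, seed=cfg.seed)

        # Module 4: parsimony sweep on the validation set
        pars = parsimony(ranking, train, valid, scheme, max_k=cfg.max_k)
        k = cfg.final_k if cfg.final_k is not None else pars.best_k()
        selected = select_variables(pars, k, include=cfg.include, exclude=cfg.exclude)

        # Modules 3 + 5: derive (and optionally fine-tune) the scoring table
        train_sel = train.select(selected)
        overrides_sel = {v: c for v, c in cfg.cutoff_overrides.items() if v in selected}
        if overrides_sel:
            table, pom_fit, cat_sel = fine_tune(overrides_sel, train_sel, scheme, cfg.rescale_target)
        else:
            table, pom_fit, cat_sel = build_scoring_table(train_sel, scheme, cfg.rescale_target)

        # lookup table from the training set
        lookup = build_lookup(table, cat_sel, bins=cfg.lookup_bins)

        # Module 6: test-set evaluation + calibration
        test_scores = table.score(test.df, coerce=True)
        report = evaluate(test_scores, test.y, n_boot=cfg.n_boot, seed=cfg.seed)
        calib = calibration_report(table, lookup, test)

        return OrdinalScoreResults(
            model=self,
            config=cfg,
            split=split,
            scheme=table.cutoff_scheme,
            ranking=ranking,
            parsimony_=pars,
            selected_variables=selected,
            pom_fit=pom_fit,
            scoring_table=table,
            lookup=lookup,
            eval_report=report,
            calibration=calib,
            train=train,
            test_scores=test_scores,
        )

    @staticmethod
    def _apply_fill(d: OrdinalData, rules: dict[str, float]) -> OrdinalData:
        if not rules:
            return d
        df = d.df.copy()
        for col, value in rules.items():
            if col in df.columns:
                df[col] = df[col].fillna(value)
        return d.with_df(df)


@dataclass
class OrdinalScoreResults:
    """Everything the workflow produced, with rendering and prediction helpers."""

    model: OrdinalScoreModel
    config: RunConfig
    split: DataSplit
    scheme: CutoffScheme
    ranking: VariableRanking
    parsimony_: ParsimonyResult
    selected_variables: list[str]
    pom_fit: POMResults
    scoring_table: ScoringTable
    lookup: LookupTable
    eval_report: EvalReport
    calibration: pd.DataFrame
    train: OrdinalData = field(repr=False)
    test_scores: np.ndarray = field(repr=False)

    # -- prediction ----------------------------------------------------------
    def predict(self, df: pd.DataFrame, coerce: bool = True) -> np.ndarray:
        """Integer total scores for new (raw, already non-missing) records."""
        data = OrdinalData(
            df.assign(**{self.model.data.outcome: 1}),
            self.model.data.outcome,
            predictors=tuple(self.selected_variables),
            categorical=tuple(
                c for c in self.model.data.categorical if c in self.selected_variables
            ),
        )
        data = impute_median(self.train, data)
        cat = apply_cutoffs(data, self.scheme)
        return self.scoring_table.score(cat.df, coerce=coerce)

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        """Outcome-category probabilities read off the lookup table."""
        return self.lookup.predict_proba(self.predict(df))

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Ordinal risk score — workflow summary",
            "=" * 52,
            f"cohort: n={self.model.data.n}, J={self.model.data.n_categories} | "
            f"split {self.config.ratios} (seed {self.config.seed})",
            f"selected variables ({len(self.selected_variables)}): "
            + ", ".join(self.selected_variables),
            "",
            self.scoring_table.to_text(),
            "",
            "Lookup table (training-set category proportions):",
            self.lookup.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            "Test-set evaluation:",
            self.eval_report.summary(),
        ]
        return "\n".join(lines)

    def run_log(self) -> dict:
        """Everything needed to reproduce the run."""
        return {
            "config": asdict(self.config),
            "split_sizes": {
                "train": int(self.split.train_idx.size),
                "valid": int(self.split.valid_idx.size),
                "test": int(self.split.test_idx.size),
            },
            "ranking": [list(t) for t in zip(self.ranking.variables, self.ranking.importances)],
            "cutoffs": self.scheme.cutoffs,
            "cutoff_provenance": self.scheme.provenance,
            "selected_variables": list(self.selected_variables),
            "pom_loglik": self.pom_fit.loglik,
            "pom_converged": self.pom_fit.converged,
            "max_total": self.scoring_table.max_total,
        }

    def save_artifacts(self, outdir: str | Path) -> Path:
        """Write every artifact (CSV/JSON/plots) of the run to ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.ranking.to_frame().to_csv(out / "ranking.csv", index=False)
        (out / "cutoffs.json").write_text(self.scheme.to_json())
        self.parsimony_.table.to_csv(out / "parsimony.csv", index=False)
        self.scoring_table.to_frame().to_csv(out / "scoring_table.csv", index=False)
        (out / "scoring_table.txt").write_text(self.scoring_table.to_text() + "\n")
        (out / "scoring_table.json").write_text(self.scoring_table.to_json())
        (out / "pom_fit.json").write_text(self.pom_fit.to_json())
        self.lookup.to_frame().to_csv(out / "lookup.csv", index=False)
        (out / "lookup.json").write_text(self.lookup.to_json())
        (out / "eval_report.json").write_text(self.eval_report.to_json())
        self.calibration.to_csv(out / "calibration.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(self.run_log(), indent=2))
        try:
            import matplotlib

            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            ax = self.parsimony_.plot()
            ax.figure.savefig(out / "parsimony.png", dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
            ax = plot_calibration(self.calibration)
            ax.figure.savefig(out / "calibration.png", dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
        except Exception:  # plotting must never sink a completed run
            pass
        return out


def run_pipeline(config: RunConfig, df: pd.DataFrame | None = None) -> OrdinalScoreResults:
    """Config-driven run: load the cohort, fit the workflow, write artifacts."""
    if df is None:
        if not config.cohort:
            raise ValueError("config.cohort (a CSV path) is required when no frame is given")
        df = pd.read_csv(config.cohort)
    config.validate_columns(df)
    model = OrdinalScoreModel.from_dataframe(
        df,
        outcome=config.outcome,
        predictors=config.predictors,
        categorical=config.categorical,
        config=config,
    )
    results = model.fit()
    results.save_artifacts(config.output_dir)
    return results
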