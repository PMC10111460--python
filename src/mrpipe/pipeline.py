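"""Study orchestration: primary analyses, multiplicity, the sensitivity suite,
bidirectional MR, covariate adjustment and mediation, driven by a YAML config.

Primary significance uses a Bonferroni threshold of 0.0125 (four exposure
hypotheses per outcome); the divisor is a configuration value, fixed rather
than recomputed, so the published design is mirrored exactly.  Bidirectional
and covariate-adjusted analyses run only for pairs passing the nominal 0.05
gate.  Per-pair failures are logged and isolated; a run never aborts wholesale
on one degenerate pair.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import MRError, ValidationError
from .estimators import egger, ivw, mr_presso, to_odds_ratio, weighted_median
from .instrumenting import (
    DROPPED_INCOMPATIBLE,
    DROPPED_MISSING_OUTCOME,
    DROPPED_PALINDROME,
    RETAINED_ACTIONS,
    overall_strength,
    select_instruments,
)
from .mvmr import mediate, mvmr_ivw, univariable_pipeline
from .summary_data import GwasTable, LDMatrix, read_gwas, read_ld

logger = logging.getLogger(__name__)


@dataclass
class TableRef:
    """Reference to one GWAS summary-statistics file plus its trait metadata."""

    name: str
    path: str
    units: str = ""
    binary: bool = False
    per_unit_decrease: bool = False
    sex: str = "both"
    column_map: Optional[dict] = None


@dataclass
class Thresholds:
    p_instrument: float = 5e-8
    r2_clump: float = 0.001
    alpha_primary: float = 0.0125
    alpha_nominal: float = 0.05
    palindrome_window: float = 0.08


@dataclass
class StudyConfig:
    tables: dict[str, TableRef]
    exposures: list[str]
    outcomes: list[str]
    mediators: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    ld_path: Optional[str] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    methods: dict = field(default_factory=lambda: {
        "weighted_median": True, "egger": True, "presso": True})
    presso_n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0

    def validate(self) -> None:
        t = self.thresholds
        if t.alpha_primary > t.alpha_nominal:
            raise ValidationError("alpha_primary must not exceed alpha_nominal")
        for group in (self.exposures, self.outcomes, self.mediators, self.covariates):
            for name in group:
                if name not in self.tables:
                    raise ValidationError(f"table reference {name!r} not defined")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        tables = {
            name: TableRef(name=name, **spec)
            for name, spec in d.get("tables", {}).items()
        }
        cfg = cls(
            tables=tables,
            exposures=list(d.get("exposures", [])),
            outcomes=list(d.get("outcomes", [])),
            mediators=list(d.get("mediators", [])),
            covariates=list(d.get("covariates", [])),
            ld_path=d.get("ld"),
            thresholds=Thresholds(**d.get("thresholds", {})),
            methods=dict(d.get("methods", {"weighted_median": True,
                                           "egger": True, "presso": True})),
            presso_n_sim=int(d.get("presso_n_sim", 1000)),
            n_boot=int(d.get("n_boot", 1000)),
            seed=int(d.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical_hash(self) -> str:
        blob = json.dumps(self, default=lambda o: o.__dict__, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class StudyReport:
    primary: pd.DataFrame = field(default_factory=pd.DataFrame)
    sensitivity: pd.DataFrame = field(default_factory=pd.DataFrame)
    bidirectional: pd.DataFrame = field(default_factory=pd.DataFrame)
    adjusted: pd.DataFrame = field(default_factory=pd.DataFrame)
    mediation: pd.DataFrame = field(default_factory=pd.DataFrame)
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("primary", "sensitivity", "bidirectional",
                     "adjusted", "mediation", "audit"):
            df = getattr(self, name)
            if not df.empty:
                df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                          float_format="%.12g", na_rep="NA")


def pair_seed(seed: int, *labels: str) -> int:
    """Stable per-analysis seed derived from the run seed and identifying labels."""
    return zlib.crc32(":".join((str(seed),) + labels).encode()) & 0x7FFFFFFF


class Study:
    """Loads the configured tables once and runs the analysis suite."""

    def __init__(self, config: StudyConfig):
        config.validate()
        self.config = config
        self._tables: dict[str, GwasTable] = {}
        self._ld: Optional[LDMatrix] = None
        self._harmonized: dict[tuple, object] = {}

    # -- data access ---------------------------------------------------------

    def table(self, name: str) -> GwasTable:
        if name not in self._tables:
            ref = self.config.tables[name]
            self._tables[name] = read_gwas(
                ref.path, column_map=ref.column_map, trait_name=name,
                trait_units=ref.units, is_binary=ref.binary, sex=ref.sex)
        return self._tables[name]

    def set_table(self, name: str, table: GwasTable) -> None:
        """Inject an in-memory table (used by tests and the simulator)."""
        self._tables[name] = table

    @property
    def ld(self) -> LDMatrix:
        if self._ld is None:
            self._ld = read_ld(self.config.ld_path) if self.config.ld_path else LDMatrix()
        return self._ld

    def set_ld(self, ld: LDMatrix) -> None:
        self._ld = ld

    def _pair(self, exp_name: str, out_name: str):
        """Cached univariable run for one exposure/outcome pair."""
        key = (exp_name, out_name)
        if key not in self._harmonized:
            t = self.config.thresholds
            result, h = univariable_pipeline(
                self.table(exp_name), self.table(out_name), self.ld,
                t.p_instrument, t.r2_clump, t.palindrome_window)
            self._harmonized[key] = (result, h)
        return self._harmonized[key]

    def _or_fields(self, result, exp_name: str, out_name: str) -> dict:
        binary = self.config.tables[out_name].binary
        if binary:
            converted = to_odds_ratio(
                result, per_unit_decrease=self.config.tables[exp_name].per_unit_decrease)
            return {"or": converted.odds_ratio, "or_low": converted.or_low,
                    "or_high": converted.or_high}
        return {"or": np.nan, "or_low": np.nan, "or_high": np.nan}

    # -- analyses ------------------------------------------------------------

    def run_primary(self) -> StudyReport:
        """IVW (Wald ratio for single instruments) per exposure/outcome pair,
        flagged at the primary (Bonferroni) and nominal thresholds, with a
        per-pair instrument audit."""
        t = self.config.thresholds
        rows, audit_rows = [], []
        for exp_name in self.config.exposures:
            for out_name in self.config.outcomes:
                try:
                    result, h = self._pair(exp_name, out_name)
                except MRError as exc:
                    logger.warning("primary %s -> %s failed: %s", exp_name, out_name, exc)
                    rows.append({"exposure": exp_name, "outcome": out_name,
                                 "method": "failed", "note": str(exc)})
                    continue
                row = {
                    "exposure": exp_name, "outcome": out_name,
                    "method": result.method, "n_snp": result.n_snp,
                    "estimate": result.estimate, "se": result.se,
                    "ci_low": result.ci_low, "ci_high": result.ci_high,
                    "pval": result.pval,
                    "sig_primary": result.pval < t.alpha_primary,
                    "sig_nominal": result.pval < t.alpha_nominal,
                    "note": "",
                }
                row.update(self._or_fields(result, exp_name, out_name))
                rows.append(row)

                counts = h.action_counts
                selected = select_instruments(self.table(exp_name), t.p_instrument)
                strength = overall_strength(h.exposure_table())
                n_harmonized = sum(counts.get(a, 0) for a in RETAINED_ACTIONS)
                audit_rows.append({
                    "exposure": exp_name, "outcome": out_name,
                    "n_selected": len(selected),
                    "n_missing_outcome": counts.get(DROPPED_MISSING_OUTCOME, 0),
                    "n_dropped_palindrome": counts.get(DROPPED_PALINDROME, 0),
                    "n_dropped_incompatible": counts.get(DROPPED_INCOMPATIBLE, 0),
                    "n_harmonized": n_harmonized,
                    "n_clumped": len(h),
                    "r2_total": strength.total_r2,
                    "f_overall": strength.overall_f,
                })
        return StudyReport(primary=pd.DataFrame(rows), audit=pd.DataFrame(audit_rows))

    def run_sensitivity(self) -> pd.DataFrame:
        """Weighted median, MR-Egger and MR-PRESSO on the shared harmonized
        sets; estimators with unmet preconditions are skipped with a reason."""
        cfg = self.config
        rows = []
        for exp_name in cfg.exposures:
            for out_name in cfg.outcomes:
                try:
                    _, h = self._pair(exp_name, out_name)
                except MRError as exc:
                    rows.append({"exposure": exp_name, "outcome": out_name,
                                 "method": "failed", "note": str(exc)})
                    continue
                base = {"exposure": exp_name, "outcome": out_name, "note": ""}
                if cfg.methods.get("weighted_median", True):
                    try:
                        wm = weighted_median(
                            h, n_boot=cfg.n_boot,
                            seed=pair_seed(cfg.seed, exp_name, out_name, "wm"))
                        rows.append({**base, "method": wm.method, "n_snp": wm.n_snp,
                                     "estimate": wm.estimate, "se": wm.se,
                                     "ci_low": wm.ci_low, "ci_high": wm.ci_high,
                                     "pval": wm.pval,
                                     **self._or_fields(wm, exp_name, out_name)})
                    except MRError as exc:
                        rows.append({**base, "method": "weighted_median",
                                     "note": f"skipped: {exc}"})
                if cfg.methods.get("egger", True):
                    try:
                        eg = egger(h)
                        rows.append({**base, "method": eg.slope.method,
                                     "n_snp": eg.slope.n_snp,
                                     "estimate": eg.slope.estimate, "se": eg.slope.se,
                                     "ci_low": eg.slope.ci_low, "ci_high": eg.slope.ci_high,
                                     "pval": eg.slope.pval,
                                     "egger_intercept": eg.intercept,
                                     "egger_intercept_se": eg.intercept_se,
                                     "egger_intercept_pval": eg.intercept_pval,
                                     **self._or_fields(eg.slope, exp_name, out_name)})
                    except MRError as exc:
                        rows.append({**base, "method": "egger_slope",
                                     "note": f"skipped: {exc}"})
                if cfg.methods.get("presso", True):
                    try:
                        pr = mr_presso(
                            h, n_sim=cfg.presso_n_sim,
                            seed=pair_seed(cfg.seed, exp_name, out_name, "presso"))
                        rows.append({**base, "method": "presso_corrected",
                                     "n_snp": pr.corrected.n_snp,
                                     "estimate": pr.corrected.estimate,
                                     "se": pr.corrected.se,
                                     "ci_low": pr.corrected.ci_low,
                                     "ci_high": pr.corrected.ci_high,
                                     "pval": pr.corrected.pval,
                                     "presso_global_pval": pr.global_pval,
                                     "presso_n_outliers": len(pr.outlier_snps),
                                     "presso_distortion_pval": pr.distortion_pval,
                                     **self._or_fields(pr.corrected, exp_name, out_name)})
                    except MRError as exc:
                        rows.append({**base, "method": "presso",
                                     "note": f"skipped: {exc}"})
        return pd.DataFrame(rows)

    def _nominal_pairs(self, primary: pd.DataFrame) -> list[tuple[str, str]]:
        if primary.empty or "sig_nominal" not in primary.columns:
            return []
        sig = primary[primary["sig_nominal"].fillna(False).astype(bool)]
        return list(zip(sig["exposure"], sig["outcome"]))

    def run_bidirectional(self, pairs) -> pd.DataFrame:
        """Rerun the univariable pipeline with exposure and outcome roles
        swapped; results are reported as beta and SE, never as OR."""
        t = self.config.thresholds
        rows = []
        for exp_name, out_name in pairs:
            try:
                result, _ = univariable_pipeline(
                    self.table(out_name), self.table(exp_name), self.ld,
                    t.p_instrument, t.r2_clump, t.palindrome_window)
                rows.append({"exposure": out_name, "outcome": exp_name,
                             "method": result.method, "n_snp": result.n_snp,
                             "estimate": result.estimate, "se": result.se,
                             "ci_low": result.ci_low, "ci_high": result.ci_high,
                             "pval": result.pval, "note": ""})
            except MRError as exc:
                logger.info("bidirectional %s -> %s skipped: %s", out_name, exp_name, exc)
                rows.append({"exposure": out_name, "outcome": exp_name,
                             "method": "skipped", "note": str(exc)})
        return pd.DataFrame(rows)

    def run_adjusted(self, pairs, covariate: str) -> pd.DataFrame:
        """Multivariable IVW with a covariate co-exposure for each pair."""
        t = self.config.thresholds
        rows = []
        for exp_name, out_name in pairs:
            try:
                mv = mvmr_ivw(
                    [self.table(exp_name), self.table(covariate)],
                    self.table(out_name), self.ld,
                    t.p_instrument, t.r2_clump, t.palindrome_window)
                eff = mv.effect(exp_name)
                row = {"exposure": exp_name, "outcome": out_name,
                       "method": "mvmr_ivw", "adjusted_for": covariate,
                       "n_snp": eff.n_snp, "estimate": eff.estimate, "se": eff.se,
                       "ci_low": eff.ci_low, "ci_high": eff.ci_high,
                       "pval": eff.pval,
                       "conditional_f": mv.conditional_f[exp_name], "note": ""}
                row.update(self._or_fields(eff, exp_name, out_name))
                rows.append(row)
            except MRError as exc:
                logger.info("adjusted %s -> %s | %s skipped: %s",
                            exp_name, out_name, covariate, exc)
                rows.append({"exposure": exp_name, "outcome": out_name,
                             "method": "skipped", "adjusted_for": covariate,
                             "note": str(exc)})
        return pd.DataFrame(rows)

    def run_mediation(self) -> pd.DataFrame:
        """Step-wise mediation for every exposure/outcome pair against the
        configured mediators; unadjusted (total) row first, then one row per
        mediator that passed the screen."""
        cfg = self.config
        t = cfg.thresholds
        rows = []
        mediator_tables = [self.table(m) for m in cfg.mediators]
        for exp_name in cfg.exposures:
            for out_name in cfg.outcomes:
                failures: dict = {}
                reports = mediate(
                    self.table(exp_name), self.table(out_name), mediator_tables,
                    self.ld, screen_alpha=t.alpha_nominal,
                    p_threshold=t.p_instrument, r2_threshold=t.r2_clump,
                    palindrome_window=t.palindrome_window, failures=failures)
                if reports:
                    total = reports[0].total
                    row = {"exposure": exp_name, "outcome": out_name,
                           "mediator": "none", "role": "total",
                           "n_snp": total.n_snp, "estimate": total.estimate,
                           "se": total.se, "ci_low": total.ci_low,
                           "ci_high": total.ci_high, "pval": total.pval,
                           "attenuation": "", "note": ""}
                    row.update(self._or_fields(total, exp_name, out_name))
                    rows.append(row)
                for rep in reports:
                    row = {"exposure": exp_name, "outcome": out_name,
                           "mediator": rep.mediator, "role": "direct",
                           "n_snp": rep.direct.n_snp,
                           "estimate": rep.direct.estimate, "se": rep.direct.se,
                           "ci_low": rep.direct.ci_low, "ci_high": rep.direct.ci_high,
                           "pval": rep.direct.pval,
                           "attenuation": rep.attenuation, "note": ""}
                    row.update(self._or_fields(rep.direct, exp_name, out_name))
                    rows.append(row)
                for med_name, reason in failures.items():
                    rows.append({"exposure": exp_name, "outcome": out_name,
                                 "mediator": med_name, "role": "failed",
                                 "note": reason})
        return pd.DataFrame(rows)

    def run_all(self) -> StudyReport:
        report = self.run_primary()
        report.sensitivity = self.run_sensitivity()
        pairs = self._nominal_pairs(report.primary)
        report.bidirectional = self.run_bidirectional(pairs)
        if self.config.covariates:
            frames = [self.run_adjusted(pairs, cov) for cov in self.config.covariates]
            report.adjusted = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        if self.config.mediators:
            report.mediation = self.run_mediation()
        return report


def write_manifest(config: StudyConfig, out_dir) -> None:
    """Deterministic run manifest: config hash, seed and library versions."""
    import scipy

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_sha256": config.canonical_hash(),
        "seed": config.seed,
        "versions": {
            "mrpipe": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
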