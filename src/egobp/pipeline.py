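"""End-to-end orchestration: validate a study bundle, then run
measures -> phasing -> phenotype -> model fitting as one reproducible run.

A *study bundle* is a directory of four CSV tables (UTF-8, comma, header
row): ``participants.csv``, ``alters.csv``, ``ties.csv``, ``genotypes.csv``
(schemas below).  A run writes ``measures.csv``, ``diplotypes.csv``,
``analysis_table.csv``, ``model_fits.json``, ``selection_trace.json``,
``tukey.json``, ``report.md`` and ``run.log`` into the output directory;
re-running with the same inputs and configuration is bit-identical except
for timestamps in the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, ego_network, haplotype, modeling, phenotype

logger = logging.getLogger(__name__)

PARTICIPANT_COLUMNS = ["participant_id", "age", "sex", "bmi", "medicated",
                       "sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3"]
ALTER_COLUMNS = ["participant_id", "alter_index", "relationship_codes",
                 "alter_age", "alter_sex", "skin_tone"]
TIE_COLUMNS = ["participant_id", "alter_i", "alter_j", "rating"]
GENOTYPE_COLUMNS = ["participant_id", "rs4313", "rs4337", "ace_alu"]


class PipelineError(RuntimeError):
    pass


@dataclass
class StudyBundle:
    participants: pd.DataFrame
    alters: pd.DataFrame
    ties: pd.DataFrame
    genotypes: pd.DataFrame

    @classmethod
    def read(cls, directory) -> "StudyBundle":
        d = Path(directory)
        def _read(name):
            path = d / name
            if not path.exists():
                raise PipelineError(f"missing input file {path}")
            return pd.read_csv(path)
        return cls(participants=_read("participants.csv"),
                   alters=_read("alters.csv"),
                   ties=_read("ties.csv"),
                   genotypes=_read("genotypes.csv"))

    @classmethod
    def from_study(cls, study) -> "StudyBundle":
        return cls(participants=study.participants, alters=study.alters,
                   ties=study.ties, genotypes=study.genotypes)


@dataclass
class RunConfig:
    tie_threshold: int = 4
    distance_convention: str = "reachable"   # or "penalized"
    coding_mode: str = "dosage"              # or "categorical"
    med_mode: str = "corrected"              # or "covariate"
    alpha: float = 0.05
    m_tests: int = 5
    one_based_alters: bool = False
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.distance_convention not in ("reachable", "penalized"):
            raise PipelineError(f"bad distance_convention {self.distance_convention!r}")
        if self.coding_mode not in ("dosage", "categorical"):
            raise PipelineError(f"bad coding_mode {self.coding_mode!r}")
        if self.med_mode not in ("corrected", "covariate"):
            raise PipelineError(f"bad med_mode {self.med_mode!r}")
        if not (0 < self.alpha < 1):
            raise PipelineError(f"alpha {self.alpha} outside (0, 1)")
        if self.m_tests < 1:
            raise PipelineError(f"m_tests must be >= 1")
        return self


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate(bundle: StudyBundle, config: RunConfig = None) -> ValidationReport:
    """Check every schema invariant; fatal errors vs warnings."""
    config = (config or RunConfig()).validate()
    rep = ValidationReport()
    err = rep.errors.append

    for name, tbl, cols in (("participants.csv", bundle.participants, PARTICIPANT_COLUMNS),
                            ("alters.csv", bundle.alters, ALTER_COLUMNS),
                            ("ties.csv", bundle.ties, TIE_COLUMNS),
                            ("genotypes.csv", bundle.genotypes, GENOTYPE_COLUMNS)):
        missing = [c for c in cols if c not in tbl.columns]
        if missing:
            err(f"{name}: missing columns {missing}")
    if rep.errors:
        return rep

    parts = bundle.participants
    if parts["participant_id"].duplicated().any():
        err("participants.csv: duplicate participant_id")
    if not parts["sex"].isin([1, 2]).all():
        err("participants.csv: sex must be coded male=1/female=2")
    if not parts["medicated"].isin([0, 1]).all():
        err("participants.csv: medicated must be 0/1")

    known = set(parts["participant_id"])
    for name, tbl in (("alters.csv", bundle.alters), ("ties.csv", bundle.ties),
                      ("genotypes.csv", bundle.genotypes)):
        orphans = set(tbl["participant_id"]) - known
        if orphans:
            err(f"{name}: unknown participant_id(s) {sorted(orphans)[:5]}")

    n_alt = ego_network.N_ALTERS
    offset = 1 if config.one_based_alters else 0
    for pid, grp in bundle.alters.groupby("participant_id"):
        idx = sorted(grp["alter_index"] - offset)
        if idx != list(range(n_alt)):
            err(f"alters.csv: ego {pid} has {len(idx)} alters "
                f"(need indices {offset}..{n_alt - 1 + offset})")
    n_pairs = ego_network.N_PAIRS
    for pid, grp in bundle.ties.groupby("participant_id"):
        if len(grp) != n_pairs:
            err(f"ties.csv: ego {pid} has {len(grp)} of {n_pairs} alter pairs")
        bad = grp[~grp["rating"].isin([1, 2, 3, 4, 5])]
        if not bad.empty:
            row = bad.iloc[0]
            err(f"ties.csv: ego {pid} pair ({row['alter_i']},{row['alter_j']}) "
                f"rating {row['rating']} outside 1-5 (line {bad.index[0] + 2})")

    for row in bundle.genotypes.itertuples(index=False):
        for marker, alleles in haplotype.ACE_MARKERS:
            try:
                haplotype.parse_genotype(getattr(row, marker), alleles, marker)
            except haplotype.GenotypeError as exc:
                err(f"genotypes.csv: participant {row.participant_id}: {exc}")

    no_net = known - set(bundle.ties["participant_id"])
    if no_net:
        rep.warnings.append(f"{len(no_net)} participants without network data")
    no_geno = known - set(bundle.genotypes["participant_id"])
    if no_geno:
        rep.warnings.append(f"{len(no_geno)} participants without genotypes")
    return rep


def _fit_to_dict(fit: modeling.FitResult) -> dict:
    return {
        "terms": list(fit.terms),
        "coefficients": {t: float(v) for t, v in fit.params.items()},
        "std_errors": {t: float(v) for t, v in fit.bse.items()},
        "p_values": {t: float(v) for t, v in fit.pvalues.items()},
        "n": fit.n, "k": fit.k, "rss": fit.rss,
        "r_squared": fit.r_squared,
        "adj_r_squared": fit.adj_r_squared,
        "aic": fit.aic,
    }


def _render_report(fits, tukey_payload, analysis_n, bonf, out_path) -> None:
    lines = ["# Blood-pressure model report", ""]
    lines.append(f"Analysis rows: {analysis_n}; Bonferroni-corrected "
                 f"significance threshold: {bonf:.4g}")
    for resp in ("sbp", "dbp"):
        lines += ["", f"## {resp.upper()} models", ""]
        lines.append("| term | " + " | ".join(
            f"{m} coef (p)" for m in ("base", "genetic", "network", "optimal")) + " |")
        lines.append("|---|" + "---|" * 4)
        all_terms = ["Intercept"]
        for m in ("base", "genetic", "network", "optimal"):
            for t in fits[resp][m]["coefficients"]:
                if t not in all_terms:
                    all_terms.append(t)
        for t in all_terms:
            cells = []
            for m in ("base", "genetic", "network", "optimal"):
                c = fits[resp][m]["coefficients"].get(t)
                p = fits[resp][m]["p_values"].get(t)
                cells.append("" if c is None else f"{c:.2f} ({p:.3g})")
            lines.append(f"| {t} | " + " | ".join(cells) + " |")
        lines.append("| adjusted R^2 | " + " | ".join(
            f"{fits[resp][m]['adj_r_squared']:.3f}" for m in
            ("base", "genetic", "network", "optimal")) + " |")
        lines.append("| AIC | " + " | ".join(
            f"{fits[resp][m]['aic']:.1f}" for m in
            ("base", "genetic", "network", "optimal")) + " |")
        cmp_ = fits[resp]["comparisons"]
        fmt = lambda p: "n/a (not nested)" if p is None else f"{p:.3g}"
        lines.append("")
        lines.append(f"Optimal vs genetic: p = {fmt(cmp_['optimal_vs_genetic_p'])}; "
                     f"optimal vs network: p = {fmt(cmp_['optimal_vs_network_p'])}")
        tk = tukey_payload[resp]
        lines.append(f"One-way ANOVA across haplotype groups: "
                     f"F = {tk['anova_f']:.2f}, p = {tk['anova_p']:.3g}")
    Path(out_path).write_text("\n".join(lines) + "\n")


def run_pipeline(bundle: StudyBundle, config: RunConfig, outdir) -> Path:
    """Execute the full analysis and write all artifacts to ``outdir``."""
    config = config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"version={__version__}", f"config={dataclasses.asdict(config)}"]

    report = validate(bundle, config)
    for w in report.warnings:
        log_lines.append(f"warning={w}")
    if not report.ok:
        raise PipelineError("validation failed: " + "; ".join(report.errors))

    ties = bundle.ties.copy()
    alters = bundle.alters.copy()
    if config.one_based_alters:
        ties[["alter_i", "alter_j"]] -= 1
        alters["alter_index"] -= 1

    try:
        measures = ego_network.compute_measures_table(
            ties, alters, threshold=config.tie_threshold,
            distance_convention=config.distance_convention)
    except Exception as exc:
        raise PipelineError(f"stage measures failed: {exc}") from exc
    measures.to_csv(outdir / "measures.csv", index=False)

    try:
        freqs, posteriors = haplotype.em_phase(bundle.genotypes)
        codings = haplotype.assign_and_code(posteriors, freqs,
                                            mode=config.coding_mode)
    except Exception as exc:
        raise PipelineError(f"stage phase failed: {exc}") from exc
    hap_tbl = pd.DataFrame(
        sorted(((hn, f) for hn, f in freqs.as_named().items()),
               key=lambda x: x[0]), columns=["haplotype", "frequency"])
    hap_tbl.to_csv(outdir / "haplotypes.csv", index=False)
    codings.to_csv(outdir / "diplotypes.csv", index=False)

    try:
        transformed = phenotype.transform_for_model(
            measures[["participant_id", "mean_betweenness", "mean_distance",
                      "pct_family", "pct_central_family"]].copy())
        table = phenotype.assemble_analysis_table(
            bundle.participants, transformed, codings, med_mode=config.med_mode)
    except Exception as exc:
        raise PipelineError(f"stage phenotype failed: {exc}") from exc
    table.to_csv(outdir / "analysis_table.csv", index=False)
    excl = table.attrs["exclusions"]
    log_lines.append(f"n_in={len(bundle.participants)}")
    log_lines.append(f"n_analyzed={len(table)}")
    for reason, count in excl.items():
        log_lines.append(f"excluded_{reason}={count}")
    n_missing_tables = len(bundle.participants) - len(table) - sum(excl.values())
    log_lines.append(f"excluded_join={n_missing_tables}")

    bonf = modeling.bonferroni_threshold(config.alpha, config.m_tests)
    fits_payload, trace_payload, tukey_payload = {}, {}, {}
    try:
        for resp in ("sbp", "dbp"):
            design = modeling.DesignSpec(response=resp)
            fits, trace = modeling.sequential_selection(design, table)
            _, _, _, p_gen = modeling.nested_f_test(fits["genetic"], fits["optimal"]) \
                if set(fits["genetic"].terms) <= set(fits["optimal"].terms) else (None,) * 4
            _, _, _, p_net = modeling.nested_f_test(fits["network"], fits["optimal"]) \
                if set(fits["network"].terms) <= set(fits["optimal"].terms) else (None,) * 4
            fits_payload[resp] = {m: _fit_to_dict(f) for m, f in fits.items()}
            fits_payload[resp]["comparisons"] = {
                "optimal_vs_genetic_p": p_gen, "optimal_vs_network_p": p_net,
                "bonferroni_threshold": bonf}
            trace_payload[resp] = {
                stage: [dataclasses.asdict(s) for s in steps]
                for stage, steps in trace.items()}
            for stage in trace_payload[resp].values():
                for s in stage:
                    s["candidate"] = list(s["candidate"])
            cat = haplotype.assign_and_code(posteriors, freqs, mode="categorical")
            merged = table.merge(cat[["participant_id", "group"]], on="participant_id")
            tk = modeling.tukey_kramer(merged["group"], merged[resp])
            tukey_payload[resp] = {
                "anova_f": tk.anova_f, "anova_p": tk.anova_p,
                "df_between": tk.df_between, "df_within": tk.df_within,
                "pairs": tk.pairs.to_dict(orient="records")}
    except Exception as exc:
        raise PipelineError(f"stage fit failed: {exc}") from exc

    (outdir / "model_fits.json").write_text(json.dumps(fits_payload, indent=1))
    (outdir / "selection_trace.json").write_text(json.dumps(trace_payload, indent=1))
    (outdir / "tukey.json").write_text(json.dumps(tukey_payload, indent=1))
    _render_report(fits_payload, tukey_payload, len(table), bonf,
                   outdir / "report.md")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    logger.info("pipeline complete: %s", outdir)
    return outdir
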