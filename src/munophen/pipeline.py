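"""One-command orchestration with config files and a reproducibility
manifest.

``run_all`` reads a YAML/JSON run configuration (or a ``RunConfig``), loads
or generates a cohort, fits the :class:`~munophen.study.MunoStudy`, and
writes the table analogs, ROC coordinates and a manifest to the output
directory.  Outputs are deterministic given (config, seed): presentation
CSVs round to 2 decimals, full-precision copies sit alongside.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datamodel import CohortTable, read_cohort, write_cohort
from .study import MunoStudy, MunoStudyResults
from .synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger("munophen")


@dataclass
class RunConfig:
    """Run configuration: either ``cohort_csv`` or generator settings."""

    output_dir: str = "munophen_out"
    cohort_csv: str | None = None
    strict: bool = True
    seed: int = 0
    n: int = 1302
    muno_target: float = 0.656
    male_fraction: float = 0.603
    log_file: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def setup_logging(log_file: str | None = None, level: int = logging.INFO) -> None:
    """Structured log to stderr and, optionally, a file."""
    logger.setLevel(logging.DEBUG)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    sh = logging.StreamHandler()
    sh.setLevel(level)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if log_file:
        fh = logging.FileHandler(log_file, mode="w")
        fh.setLevel(logging.DEBUG)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


def _load_cohort(config: RunConfig) -> CohortTable:
    if config.cohort_csv:
        return read_cohort(config.cohort_csv, strict=config.strict)
    gen = GeneratorConfig(n=config.n, seed=config.seed,
                          male_fraction=config.male_fraction,
                          muno_target=config.muno_target)
    return generate_cohort(gen)


def _write_rounded(df: pd.DataFrame, path: Path) -> None:
    df.round(2).to_csv(path, index=False)


def run_all(config: RunConfig | str | Path) -> tuple[Path, MunoStudyResults]:
    """Execute the full pipeline and write all outputs.

    Emits ``table1.csv`` ... ``table4.csv`` (2-decimal presentation),
    ``*_full.csv`` full-precision copies, ``roc_points.csv`` and
    ``manifest.json``.  Returns the output directory and the fitted
    results.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_file(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(config.log_file)

    cohort = _load_cohort(config)
    analysis_cols = [c for c in cohort.data.columns
                     if c not in ("destined_muno", "scenario_label")]
    cohort = CohortTable(cohort.data[analysis_cols], provenance=cohort.provenance)
    results = MunoStudy(cohort).fit()

    outputs = []
    for name, table in [("table1", results.table1), ("table2", results.table2),
                        ("table3", results.table3), ("table4", results.table4)]:
        _write_rounded(table, outdir / f"{name}.csv")
        table.to_csv(outdir / f"{name}_full.csv", index=False)
        outputs += [f"{name}.csv", f"{name}_full.csv"]

    rows = []
    for (stratum, index_name), pts in results.roc_curves.items():
        for fpr, tpr in pts:
            rows.append({"stratum": stratum, "index": index_name,
                         "fpr": fpr, "tpr": tpr})
    pd.DataFrame(rows).to_csv(outdir / "roc_points.csv", index=False)
    outputs.append("roc_points.csv")

    write_cohort(cohort, outdir / "cohort_input.csv")
    outputs.append("cohort_input.csv")

    excl = results.exclusions
    manifest = {
        "software": {"name": "munophen", "version": __version__},
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "input_provenance": cohort.provenance,
        "counts": {
            "input": excl.n_input,
            "analyzed": excl.n_retained,
            "excluded": excl.counts,
        },
        "prevalence": results.prevalence,
        "outputs": sorted(outputs),
    }
    assert excl.n_input == excl.n_retained + excl.n_excluded
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run_all: wrote %d outputs to %s", len(outputs) + 1, outdir)
    return outdir, results
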