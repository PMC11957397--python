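"""End-to-end imputation pipeline and run configuration.

``run_impute`` wires the stages together: preprocess -> flag
non-biological zeros -> build phylogenetic hierarchy -> Gibbs-sample the
hierarchical factorization -> write the imputed matrix, diagnostics and a
manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .engine import EngineConfig, ImputationResult, build_levels, impute, run_chain
from .hierarchy import build_hierarchy, default_cut_heights, distances_from_tree
from .io import (
    read_count_matrix,
    read_covariates,
    read_distance_matrix,
    write_flag_report,
    write_hierarchy,
    write_matrix,
)
from .preprocessing import (
    DEFAULT_LIBRARY_SIZE,
    DEFAULT_OFFSET,
    LogMatrix,
    log_transform,
    mark_missing,
    normalize_counts,
)
from .zero_identification import CovariateTable, EMConfig, flag_nonbiological_zeros

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_impute", "derive_seeds"]


@dataclass
class RunConfig:
    counts_path: str
    output_dir: str
    covariates_path: str | None = None
    tree_path: str | None = None
    distances_path: str | None = None
    orientation: str = "samples-rows"
    library_size: float = DEFAULT_LIBRARY_SIZE
    offset: float = DEFAULT_OFFSET
    em: EMConfig = field(default_factory=EMConfig)
    filter_confidence: float = 0.95
    e_threshold: float = 0.5
    lrt_alpha: float = 0.05
    cut_quantiles: tuple[float, float, float] = (0.25, 0.5, 0.75)
    cut_heights: tuple[float, float, float] | None = None
    engine: EngineConfig = field(default_factory=EngineConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        em = EMConfig(**raw.pop("em", {}))
        engine = EngineConfig(**raw.pop("engine", {}))
        for key in ("cut_quantiles", "cut_heights"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(em=em, engine=engine, **raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def derive_seeds(global_seed: int, n: int) -> list[int]:
    """Deterministic per-stage substreams below 2**31 so toggling one
    stage never perturbs another's randomness."""
    ss = np.random.SeedSequence(global_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_impute(config: RunConfig) -> ImputationResult:
    """Execute the full pipeline and write artifacts under output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed, 4)
    stage = "read"
    try:
        counts = read_count_matrix(config.counts_path, config.orientation)
        covariates = None
        if config.covariates_path:
            df = read_covariates(config.covariates_path, counts.sample_ids)
            covariates = CovariateTable.from_dataframe(df)

        stage = "preprocess"
        normalized = normalize_counts(counts, config.library_size)
        logmat = log_transform(normalized, config.offset, config.library_size)

        stage = "flag"
        em = dataclasses.replace(config.em, seed=seeds[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flag_report = flag_nonbiological_zeros(
                logmat,
                covariates,
                em,
                e_threshold=config.e_threshold,
                lrt_alpha=config.lrt_alpha,
                filter_confidence=config.filter_confidence,
            )
        logmat = mark_missing(logmat, flag_report.flags)
        write_flag_report(
            flag_report, logmat, out / "flags.tsv", out / "fit_summary.tsv"
        )

        stage = "hierarchy"
        hierarchy = None
        if config.tree_path:
            distances = distances_from_tree(Path(config.tree_path).read_text())
            distances = distances.reorder(counts.taxon_ids)
        elif config.distances_path:
            distances = read_distance_matrix(config.distances_path)
            distances = distances.reorder(counts.taxon_ids)
        else:
            distances = None
            logger.warning(
                "no tree or distance matrix supplied; "
                "falling back to a single-level (plain PMF) model"
            )
        if distances is not None:
            heights = config.cut_heights or default_cut_heights(
                distances, config.cut_quantiles
            )
            hierarchy = build_hierarchy(distances, heights)
            write_hierarchy(hierarchy, out / "hierarchy.tsv")

        stage = "engine"
        engine = dataclasses.replace(config.engine, seed=seeds[1])
        data_levels, maps = build_levels(
            normalized, flag_report.flags, hierarchy,
            config.offset, config.library_size,
        )
        chain = run_chain(data_levels, maps, engine)
        finest = LogMatrix(
            data_levels[-1].values,
            list(normalized.sample_ids),
            list(normalized.taxon_ids),
            offset=config.offset,
            library_size=config.library_size,
            missing_mask=flag_report.flags,
        )
        result = impute(chain, flag_report.flags, finest)

        stage = "write"
        write_matrix(result.imputed, out / "imputed.tsv")
        sd = result.posterior_sd
        np.savetxt(out / "posterior_sd.tsv", sd, delimiter="\t")
        np.savetxt(out / "objective_trace.csv", chain.diagnostics, delimiter=",")
        manifest = {
            "tphpmf_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "config": _jsonable(config.resolved()),
            "derived_seeds": seeds,
            "n_flagged": int(flag_report.flags.sum()),
            "n_levels": len(data_levels),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
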