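"""End-to-end orchestration: counts -> correlations -> clusters -> modules -> comparisons.

The full analysis, per group and pooled: normalize counts, build observation
matrices, compute inter-regional Pearson matrices, hierarchically cluster
regions, build r-thresholded networks, run the Louvain gamma-stability sweep
and module detection, and compare the module of interest across groups with
Fisher z statistics and paired t-tests.  Every random step is keyed to the
config seed and a manifest records all options, so reruns are bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .community import (GammaSelectionError, gamma_sweep, louvain,
                        select_stable_plateau)
from .connectivity import (DEFAULT_THRESHOLDS, CorrelationMatrix,
                           pearson_matrix, threshold_network)
from .clustering import average_linkage, distance_matrix
from .data_model import (CountTable, build_observation_matrix,
                         canonical_group, canonical_region, normalize_counts,
                         read_counts)
from .group_compare import compare_module_strength, zdiff_long, zdiff_matrix
from .synthetic import NPA_MODULE

logger = logging.getLogger("iegnet")


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    normalization: str = "zscore_per_ieg_region"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    gamma_min: float = 0.1
    gamma_max: float = 2.0
    gamma_step: float = 0.01
    sweep_runs: int = 100
    scheme: str = "negative_asym"
    module_of_interest: tuple[str, ...] = tuple(sorted(NPA_MODULE))
    reference_group: str = "NPA"
    seed: int = 0
    centered_distance: bool = False

    def __post_init__(self) -> None:
        self.thresholds = tuple(sorted(float(t) for t in self.thresholds))
        self.module_of_interest = tuple(canonical_region(r)
                                        for r in self.module_of_interest)
        self.reference_group = canonical_group(self.reference_group)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def run_pipeline(config: PipelineConfig, outdir, table: CountTable | None = None) -> dict:
    """Run the full analysis and write a report bundle under ``outdir``.

    Returns the manifest dict.  On any stage failure the partially written
    output directory is removed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "options": {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(config).items()},
        "outputs": [],
        "selected_gamma": {},
        "stages": [],
    }

    def emit(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(outdir)))

    try:
        if table is None:
            if config.counts_path is None:
                raise ValueError("either a counts file or an in-memory table is required")
            table = read_counts(config.counts_path)
        stage_t = time.time()
        table = normalize_counts(table, config.normalization)
        manifest["stages"].append({"stage": "normalize", "secs": time.time() - stage_t})

        group_sets: list[tuple[str, list[str] | None]] = [("ALL", None)]
        group_sets += [(g, [g]) for g in table.groups]

        matrices: dict[str, CorrelationMatrix] = {}
        for label, groups in group_sets:
            stage_t = time.time()
            obs = build_observation_matrix(table, groups=groups)
            C = pearson_matrix(obs)
            matrices[label] = C
            C.to_csv(outdir / f"correlation_{label}.csv")
            emit(outdir / f"correlation_{label}.csv")

            dend = average_linkage(distance_matrix(obs, centered=config.centered_distance))
            (outdir / f"dendrogram_{label}.nwk").write_text(dend.to_newick() + "\n")
            emit(outdir / f"dendrogram_{label}.nwk")
            dend.merge_table().to_csv(outdir / f"merges_{label}.csv", index=False)
            emit(outdir / f"merges_{label}.csv")

            for thr in config.thresholds:
                net = threshold_network(C, thr)
                p = outdir / f"network_{label}_r{thr:.2f}.tsv"
                net.write_edgelist(p)
                emit(p)
                net.write_graphml(outdir / f"network_{label}_r{thr:.2f}.graphml")
                emit(outdir / f"network_{label}_r{thr:.2f}.graphml")

            W = C.to_numpy()
            profile = gamma_sweep(
                W, regions=C.labels, gamma_min=config.gamma_min,
                gamma_max=config.gamma_max, step=config.gamma_step,
                runs=config.sweep_runs, base_seed=config.seed,
                scheme=config.scheme)
            profile.to_csv(outdir / f"gamma_stability_{label}.csv")
            emit(outdir / f"gamma_stability_{label}.csv")
            try:
                sel = select_stable_plateau(profile)
                gamma = sel.gamma
                gamma_info = {"gamma": gamma, "source": "stable_plateau",
                              "plateau": [sel.gamma_lo, sel.gamma_hi]}
            except GammaSelectionError as err:
                gamma = err.best_gamma
                gamma_info = {"gamma": gamma, "source": "max_ami_fallback"}
                logger.warning("group %s: %s; using max-AMI gamma %.2f",
                               label, err, gamma)
            manifest["selected_gamma"][label] = gamma_info
            part = louvain(W, regions=C.labels, gamma=gamma,
                           seed=config.seed + 1, scheme=config.scheme)
            part.to_json(outdir / f"partition_{label}.json")
            emit(outdir / f"partition_{label}.json")
            part.to_csv(outdir / f"partition_{label}.csv")
            emit(outdir / f"partition_{label}.csv")
            manifest["stages"].append({"stage": f"analyze_{label}",
                                       "secs": time.time() - stage_t})
            logger.info("group %s analysed in %.1fs (gamma=%.2f)",
                        label, time.time() - stage_t, gamma)

        per_group = {g: matrices[g] for g in table.groups}
        module = list(config.module_of_interest)
        if len(per_group) >= 2:
            stage_t = time.time()
            groups = list(per_group)
            for i, g1 in enumerate(groups):
                for g2 in groups[i + 1:]:
                    zd = zdiff_matrix(per_group[g1], per_group[g2], regions=module)
                    p = outdir / f"zdiff_{g1}_vs_{g2}.csv"
                    zd.to_csv(p, float_format="%.6g")
                    emit(p)
                    zl = zdiff_long(per_group[g1], per_group[g2], regions=module)
                    p = outdir / f"zdiff_{g1}_vs_{g2}_long.csv"
                    zl.to_csv(p, index=False, float_format="%.6g")
                    emit(p)
            if config.reference_group in per_group:
                res = compare_module_strength(per_group, module,
                                              reference=config.reference_group)
                res.comparisons.to_csv(outdir / "module_strength.csv", index=False,
                                       float_format="%.6g")
                emit(outdir / "module_strength.csv")
                manifest["module_mean_r"] = res.mean_r
            manifest["stages"].append({"stage": "group_compare",
                                       "secs": time.time() - stage_t})

        manifest["total_secs"] = time.time() - t0
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception:
        # do not leave a half-written bundle behind
        for p in manifest["outputs"]:
            try:
                (outdir / p).unlink(missing_ok=True)
            except OSError:
                pass
        raise
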