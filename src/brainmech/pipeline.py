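"""End-to-end orchestration: generate -> compile -> SOM rank -> PCA -> GK-FCM.

One :class:`PipelineConfig` drives every stage for any selection of the
seven analysis subsets; a global seed deterministically derives the
per-stage, per-subset seeds so a rerun with the same config is
byte-identical.  Artifacts (ranking tables, PCA models, fuzzy partitions,
cluster characterizations, a run manifest) are written to the output
directory per subset.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compilation import CompiledDataset, split_subsets, SUBSET_INPUTS
from .fcm import FuzzyPartition, cluster_summary, select_cluster_count
from .generate import GeneratorParams, generate_dataset, write_records_csv
from .pca import (DEFAULT_COMPONENT_CAP, DEFAULT_VARIANCE_THRESHOLD, PcaModel,
                  fit_pca, select_components, transform)
from .som import SensitivityRanking, SomTrainParams, rank_features
from .studies import default_study_table

logger = logging.getLogger(__name__)

ALL_SUBSETS = list(SUBSET_INPUTS)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "brainmech_out"
    subsets: list[str] = field(default_factory=lambda: list(ALL_SUBSETS))
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    som: SomTrainParams = field(default_factory=SomTrainParams)
    som_restarts: int = 10
    som_grid: tuple[int, int] = (10, 10)
    som_max_rows: int = 1500          # seeded subsample cap for the ranking stage
    pca_threshold: float = DEFAULT_VARIANCE_THRESHOLD
    pca_cap: int = DEFAULT_COMPONENT_CAP
    fcm_c_range: tuple[int, int] = (2, 6)
    fcm_q: float = 2.0
    fcm_restarts: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "generator" in raw:
            raw["generator"] = GeneratorParams(**raw["generator"])
        if "som" in raw:
            raw["som"] = SomTrainParams(**raw["som"])
        for key in ("som_grid", "fcm_c_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        return d


@dataclass
class ReportBundle:
    rankings: dict[str, SensitivityRanking]
    pca_models: dict[str, PcaModel]
    partitions: dict[str, FuzzyPartition]
    summaries: dict[str, pd.DataFrame]
    manifest: dict


def _stage_seed(global_seed: int, stage: str, subset: str) -> int:
    h = abs(hash((stage, subset))) % (2 ** 16)
    return int(np.random.SeedSequence([global_seed, h]).generate_state(1)[0] % (2 ** 31))


def run(config: PipelineConfig) -> ReportBundle:
    """Run every stage for the selected subsets and write all artifacts."""
    unknown = set(config.subsets) - set(ALL_SUBSETS)
    if unknown:
        raise ValueError(f"unknown subsets: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gen = dataclasses.replace(config.generator, seed=_stage_seed(config.seed, "generate", "*"))
    records = generate_dataset(default_study_table(), gen)
    write_records_csv(records, out / "records.csv")
    subsets = split_subsets(records)
    for name in config.subsets:
        subsets[name].write(out / "subsets")

    rankings, pca_models, partitions, summaries = {}, {}, {}, {}
    for name in config.subsets:
        ds = subsets[name]
        logger.info("subset %s: %d rows, %d inputs", name, ds.n_rows, len(ds.input_names))
        sub_dir = out / name
        sub_dir.mkdir(exist_ok=True)

        rank_ds = _capped(ds, config.som_max_rows, _stage_seed(config.seed, "somsub", name))
        som_params = dataclasses.replace(config.som, seed=_stage_seed(config.seed, "som", name))
        ranking = rank_features(rank_ds, som_params, n_restarts=config.som_restarts,
                                grid_rows=config.som_grid[0], grid_cols=config.som_grid[1])
        ranking.write_csv(sub_dir / "ranking.csv")
        rankings[name] = ranking

        model = fit_pca(ds.matrix)
        k = select_components(model, config.pca_threshold, config.pca_cap)
        model.to_json(sub_dir / "pca.json")
        scores = transform(model, ds.matrix, k)
        pca_models[name] = model

        c_lo, c_hi = config.fcm_c_range
        c_hi = min(c_hi, ds.n_rows - 1)
        C, fits = select_cluster_count(scores, range(c_lo, c_hi + 1), Q=config.fcm_q,
                                       seeds=config.fcm_restarts,
                                       seed=_stage_seed(config.seed, "fcm", name))
        part = fits[C]
        part.to_json(sub_dir / "partition.json")
        partitions[name] = part

        summary = cluster_summary(part, ds.denormalized())
        summary.to_csv(sub_dir / "clusters.csv")
        summaries[name] = summary

    manifest = config.manifest()
    manifest["n_records"] = int(len(records))
    manifest["subset_rows"] = {n: int(subsets[n].n_rows) for n in config.subsets}
    manifest["selected_clusters"] = {n: int(p.C) for n, p in partitions.items()}
    manifest["pca_k"] = {n: int(m.k_retained) for n, m in pca_models.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    bundle = ReportBundle(rankings, pca_models, partitions, summaries, manifest)
    (out / "ranking_table.txt").write_text(report_rank_table(list(rankings.values())))
    return bundle


def _capped(ds: CompiledDataset, max_rows: int, seed: int) -> CompiledDataset:
    if max_rows <= 0 or ds.n_rows <= max_rows:
        return ds
    rng = np.random.default_rng(seed)
    idx = rng.choice(ds.n_rows, size=max_rows, replace=False)
    return CompiledDataset(matrix=ds.matrix[idx], column_names=ds.column_names,
                           peaks=ds.peaks, subset_label=ds.subset_label)


def report_rank_table(rankings: list[SensitivityRanking]) -> str:
    """Cross-subset rank table; tied features share a cell ('a + b (tied)')."""
    if not rankings:
        raise ValueError("no rankings to report")
    n_ranks = max(len(r.ranked_groups) for r in rankings)
    header = ["Rank"] + [r.subset_name for r in rankings]
    rows = []
    for i in range(n_ranks):
        row = [str(i + 1)]
        for r in rankings:
            if i < len(r.ranked_groups):
                group = r.ranked_groups[i]
                cell = " + ".join(group) + (" (tied)" if len(group) > 1 else "")
            else:
                cell = ""
            row.append(cell)
        rows.append(row)
    widths = [max(len(r[j]) for r in [header] + rows) for j in range(len(header))]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    lines = [fmt.format(*header), fmt.format(*["-" * w for w in widths])]
    lines += [fmt.format(*row) for row in rows]
    return "\n".join(lines) + "\n"
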