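"""End-to-end analysis pipeline.

Runs ingest -> networks -> individual centrality + social rank -> group
metrics -> correlation tables -> trait derivation -> between-pen
comparison, and writes one CSV per output table plus a run manifest. The
pipeline is a pure function of its inputs: rerunning on identical inputs
with the same seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import pandas as pd

from . import association, group_metrics as gm, hierarchy, network_compare
from .centrality import MEASURES, centrality_table
from .ingest import (
    ObservationRecord,
    PenNetwork,
    PenRoster,
    build_pen_network,
    read_observations,
    read_roster,
    tally_behaviour_types,
)
from .synthetic import SyntheticStudy
from .traits import TRAIT_COLUMNS, trait_table

__all__ = ["RunManifest", "run_pipeline", "run_pipeline_from_files"]

log = logging.getLogger("agonet")

_FLOAT_FMT = "%.10g"


@dataclass
class RunManifest:
    """Provenance record written alongside every pipeline run."""

    version: str
    seed: int | None
    config: dict
    input_digests: dict[str, str]
    row_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)
            + "\n"
        )


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path, manifest: RunManifest,
               *, index: bool = False) -> None:
    frame.to_csv(path, index=index, float_format=_FLOAT_FMT)
    manifest.outputs.append(path.name)
    manifest.row_counts[path.name] = len(frame)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %-16s %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


def run_pipeline(
    records: list[ObservationRecord],
    rosters: list[PenRoster],
    out_dir: str | Path,
    *,
    feeder: pd.DataFrame | None = None,
    weights: pd.DataFrame | None = None,
    backfat: pd.DataFrame | None = None,
    seed: int | None = None,
    config: dict | None = None,
    input_digests: dict[str, str] | None = None,
    make_plots: bool = False,
) -> RunManifest:
    """Run the full analysis and write the output bundle to ``out_dir``.

    Outputs: behaviour_tally.csv, centrality_ranks.csv, rank_summary.csv,
    individual_correlations.csv, group_metrics.csv, communities.csv,
    modularity.csv, traits.csv + trait_correlations.csv (when raw trait
    inputs are given), hamming_n<size>.csv + mds_n<size>.csv per
    equal-size pen group, and manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        version = metadata.version("agonet")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = RunManifest(
        version=version,
        seed=seed,
        config=config or {},
        input_digests=input_digests or {},
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        networks = _build_networks(records, rosters)
        manifest.row_counts["observations"] = len(records)
        manifest.row_counts["pens"] = len(networks)

        _tally_stage(records, out, manifest)
        cent = _centrality_stage(networks, out, manifest)
        _group_stage(networks, out, manifest)
        _individual_corr_stage(cent, out, manifest)
        if feeder is not None and weights is not None and backfat is not None:
            traits = _traits_stage(feeder, weights, backfat, out, manifest)
            _trait_corr_stage(cent, traits, out, manifest)
        _compare_stage(networks, out, manifest, make_plots=make_plots)

        manifest.warnings = sorted({str(w.message) for w in caught})
    manifest.write(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest


@_stage("networks")
def _build_networks(
    records: list[ObservationRecord], rosters: list[PenRoster]
) -> list[PenNetwork]:
    by_pen: dict[str, list[ObservationRecord]] = {r.pen_id: [] for r in rosters}
    for rec in records:
        if rec.pen_id not in by_pen:
            raise ValueError(f"record for unknown pen {rec.pen_id!r}")
        by_pen[rec.pen_id].append(rec)
    return [build_pen_network(by_pen[r.pen_id], r) for r in rosters]


@_stage("behaviour_tally")
def _tally_stage(records, out: Path, manifest: RunManifest) -> None:
    if not records:
        return
    tally = tally_behaviour_types(records)
    frame = pd.DataFrame(
        {"behaviour": list(tally), "proportion": list(tally.values())}
    )
    _write_csv(frame, out / "behaviour_tally.csv", manifest)


@_stage("centrality")
def _centrality_stage(
    networks: list[PenNetwork], out: Path, manifest: RunManifest
) -> pd.DataFrame:
    tables = []
    for net in networks:
        table = centrality_table(net)
        ranks = hierarchy.classify_pen(table)
        table["si"] = [r.si for r in ranks]
        table["category"] = [r.category for r in ranks]
        tables.append(table)
    cent = pd.concat(tables, ignore_index=True)
    _write_csv(cent, out / "centrality_ranks.csv", manifest)

    all_ranks = [
        hierarchy.SocialRank(a, s, c)
        for a, s, c in zip(cent["animal_id"], cent["si"], cent["category"])
    ]
    props = hierarchy.category_proportions(
        [hierarchy.SocialRank(r.animal_id, None if pd.isna(r.si) else r.si,
                              r.category) for r in all_ranks]
    )
    summary = pd.DataFrame(
        {"category": list(props), "percent": list(props.values())}
    )
    _write_csv(summary, out / "rank_summary.csv", manifest)
    return cent


@_stage("group_metrics")
def _group_stage(
    networks: list[PenNetwork], out: Path, manifest: RunManifest
) -> None:
    metrics = [gm.group_metrics(net) for net in networks]
    _write_csv(gm.group_metrics_frame(metrics), out / "group_metrics.csv",
               manifest)
    _write_csv(
        pd.DataFrame(
            [
                {"pen_id": m.pen_id, "modularity": m.modularity,
                 "n_communities": m.n_communities}
                for m in metrics
            ]
        ),
        out / "modularity.csv",
        manifest,
    )
    _write_csv(
        pd.DataFrame(
            [
                {"pen_id": m.pen_id, "animal_id": a, "community": c}
                for m in metrics
                for a, c in m.partition.items()
            ]
        ),
        out / "communities.csv",
        manifest,
    )


@_stage("individual_correlations")
def _individual_corr_stage(
    cent: pd.DataFrame, out: Path, manifest: RunManifest
) -> None:
    grid = association.correlation_matrix(cent[list(MEASURES)])
    _write_csv(grid.to_frame(), out / "individual_correlations.csv", manifest)


@_stage("traits")
def _traits_stage(
    feeder: pd.DataFrame, weights: pd.DataFrame, backfat: pd.DataFrame,
    out: Path, manifest: RunManifest,
) -> pd.DataFrame:
    traits = trait_table(weights, backfat, feeder)
    _write_csv(traits, out / "traits.csv", manifest, index=True)
    return traits


@_stage("trait_correlations")
def _trait_corr_stage(
    cent: pd.DataFrame, traits: pd.DataFrame, out: Path, manifest: RunManifest
) -> None:
    scores = cent.set_index("animal_id")[list(MEASURES)]
    cols = [c for c in TRAIT_COLUMNS if c in traits.columns]
    grid = association.trait_correlation_table(scores, traits[cols])
    _write_csv(grid.to_frame(), out / "trait_correlations.csv", manifest)


@_stage("compare")
def _compare_stage(
    networks: list[PenNetwork], out: Path, manifest: RunManifest,
    *, make_plots: bool = False,
) -> None:
    by_size: dict[int, list[PenNetwork]] = {}
    for net in networks:
        by_size.setdefault(net.n, []).append(net)
    for size in sorted(by_size):
        nets = by_size[size]
        if len(nets) < 2:
            warnings.warn(
                f"only one pen with {size} animals: skipped in comparison",
                stacklevel=2,
            )
            continue
        dist = network_compare.group_distance_matrix(nets)
        _write_csv(dist, out / f"hamming_n{size}.csv", manifest, index=True)
        if len(nets) > 2:
            proj = network_compare.classical_mds(dist, k=2)
            coords = proj.coords.copy()
            coords.index.name = "pen_id"
            _write_csv(coords, out / f"mds_n{size}.csv", manifest, index=True)
            if make_plots:
                _plot_mds(coords, out / f"mds_n{size}.png", size)


def _plot_mds(coords: pd.DataFrame, path: Path, size: int) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(coords["dim1"], coords["dim2"])
    for pen, row in coords.iterrows():
        ax.annotate(str(pen), (row["dim1"], row["dim2"]), fontsize=8,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.set_title(f"MDS of Hamming distances, pens of {size}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline_from_files(
    observations: str | Path,
    roster: str | Path,
    out_dir: str | Path,
    *,
    feeder: str | Path | None = None,
    weights: str | Path | None = None,
    backfat: str | Path | None = None,
    columns: dict | None = None,
    non_identified_policy: str = "drop",
    seed: int | None = None,
    config: dict | None = None,
    make_plots: bool = False,
) -> RunManifest:
    """File-based entry point: read the CSV inputs, then run the pipeline."""
    digests = {}
    paths = {"observations": Path(observations), "roster": Path(roster)}
    for name, p in (("feeder", feeder), ("weights", weights),
                    ("backfat", backfat)):
        if p is not None:
            paths[name] = Path(p)
    for name, p in paths.items():
        digests[name] = _digest_file(p)
    records, report = read_observations(
        paths["observations"], columns=(config or {}).get("columns", columns),
        non_identified_policy=non_identified_policy,
    )
    rosters = read_roster(paths["roster"])
    manifest = run_pipeline(
        records,
        rosters,
        out_dir,
        feeder=pd.read_csv(paths["feeder"]) if feeder else None,
        weights=pd.read_csv(paths["weights"]) if weights else None,
        backfat=pd.read_csv(paths["backfat"]) if backfat else None,
        seed=seed,
        config=config,
        input_digests=digests,
        make_plots=make_plots,
    )
    manifest.row_counts["rejected_rows"] = report.n_rejected
    manifest.write(Path(out_dir) / "manifest.json")
    return manifest


def run_pipeline_from_study(
    study: SyntheticStudy, out_dir: str | Path, *, make_plots: bool = False
) -> RunManifest:
    """Run the pipeline directly on an in-memory synthetic study."""
    return run_pipeline(
        study.records,
        study.rosters,
        out_dir,
        feeder=study.feeder.rename(columns={"animal": "animal"}),
        weights=study.weights,
        backfat=study.backfat,
        seed=study.seed,
        config={"synthetic": True, "pen_sizes": list(study.config.pen_sizes)},
        make_plots=make_plots,
    )
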