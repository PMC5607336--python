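"""End-to-end pipeline orchestration.

The chain runs as restartable stages -- geometry, irradiate, direct, chem,
indirect, score, yield -- each reading its inputs from the files the
previous stage wrote, so any stage can be rerun independently and
reproduces its outputs bit-exactly (per-stage random streams are spawned
deterministically from the run seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemistry import (ChemistryConfig, EVENT_COLUMNS, ReactionTable,
                        default_reactions, run_chemistry,
                        score_indirect_breaks)
from .config import RunConfig
from .direct import (SB_COLUMNS, DirectCriterion, accumulate_backbone_energy,
                     dedupe_breaks, score_direct_breaks)
from .errors import ConfigurationError, DnaDamageError
from .geometry import (TerritorySpec, build_nucleus, default_territories,
                       read_geometry, write_geometry)
from .scoring import (YieldParams, YieldResult, apply_detection_threshold,
                      cluster_breaks, clusters_table, compute_fragments,
                      dsb_yield_normalization)
from .tracks import (DEPOSIT_COLUMNS, RADIOLYSIS_COLUMNS, SourceConfig,
                     irradiate, partition_datasets)

STAGES = ("geometry", "irradiate", "direct", "chem", "indirect", "score",
          "yield")

_STR_COLS = {"chromosome": str, "kind": str, "label": str, "particle": str,
             "reactant_a": str, "reactant_b": str, "products": str}


def _read_csv(path, columns):
    dtypes = {k: v for k, v in _STR_COLS.items() if k in columns}
    try:
        df = pd.read_csv(path, dtype=dtypes, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    return df


class Pipeline:
    """Stage driver bound to one run configuration and output directory."""

    def __init__(self, config: RunConfig, output_dir=None):
        self.config = config
        self.outdir = Path(output_dir or config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        children = np.random.SeedSequence(config.seed).spawn(len(STAGES))
        self._stage_seed = dict(zip(STAGES, children))
        self._model = None
        self._index = None

    def path(self, name: str) -> Path:
        return self.outdir / name

    def _rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self._stage_seed[stage])

    # -- stages -------------------------------------------------------------

    def stage_geometry(self):
        cfg = self.config.geometry
        if cfg.path is not None:
            model = read_geometry(cfg.path)
        else:
            terrs = ([TerritorySpec(c, n) for c, n in cfg.territories]
                     if cfg.territories is not None else default_territories())
            voxel_specs = None
            if cfg.voxel_specs is not None:
                from dataclasses import replace

                from .geometry.voxel import VoxelSpec
                voxel_specs = {
                    kind: replace(VoxelSpec.default(kind), **overrides)
                    for kind, overrides in cfg.voxel_specs.items()}
                for kind in ("straight", "up", "down", "right", "left"):
                    voxel_specs.setdefault(kind, VoxelSpec.default(kind))
            model = build_nucleus(
                terrs, self._rng("geometry"),
                half_axes_nm=np.array(cfg.half_axes_um) * 1000.0,
                domain_radius_nm=cfg.domain_radius_nm,
                voxel_specs=voxel_specs)
        write_geometry(model, self.path("geometry.txt"))
        self._model, self._index = model, None
        return model

    def _load_model(self):
        if self._model is None:
            self._model = read_geometry(self.path("geometry.txt"))
        if self._index is None:
            self._index = self._model.build_index()
        return self._model, self._index

    def _source(self) -> SourceConfig:
        s = self.config.source
        return SourceConfig(
            square_x_um=s.square_x_um, square_y_um=s.square_y_um,
            proton_energy_mev=s.proton_energy_mev,
            let_kev_per_um=s.let_kev_per_um,
            deposit_min_ev=s.deposit_min_ev,
            deposit_mean_ev=s.deposit_mean_ev,
            deposit_max_ev=s.deposit_max_ev,
            sigma_lateral_nm=s.sigma_lateral_nm)

    def stage_irradiate(self):
        model, index = self._load_model()
        deposits, radiolysis = irradiate(
            self._source(), model.half_axes_nm,
            self.config.source.n_events, self._rng("irradiate"), index)
        ds1, ds2 = partition_datasets(deposits, radiolysis)
        ds1.to_csv(self.path("dataset1_dna_deposits.csv"), index=False)
        ds2.to_csv(self.path("dataset2_radiolysis.csv"), index=False)
        meta = dict(n_events=self.config.source.n_events,
                    seed=self.config.seed,
                    let_kev_per_um=self._source().let_kev_per_um,
                    config_hash=self.config.config_hash(),
                    version=__version__)
        with open(self.path("run_meta.json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
        return ds1, ds2

    def stage_direct(self):
        ds1 = _read_csv(self.path("dataset1_dna_deposits.csv"),
                        DEPOSIT_COLUMNS)
        d = self.config.direct
        criterion = DirectCriterion(mode=d.mode, threshold_ev=d.threshold_ev,
                                    linear_lo_ev=d.linear_lo_ev,
                                    linear_hi_ev=d.linear_hi_ev)
        energy = accumulate_backbone_energy(ds1, d.include_labels)
        sbs = score_direct_breaks(energy, criterion, self._rng("direct"))
        sbs.to_csv(self.path("sb_direct.csv"), index=False)
        return sbs

    def stage_chem(self):
        _, index = self._load_model()
        ds2 = _read_csv(self.path("dataset2_radiolysis.csv"),
                        RADIOLYSIS_COLUMNS)
        cfg = ChemistryConfig(t_end_ns=self.config.chemistry.t_end_ns,
                              boundary=self.config.chemistry.boundary)
        reactions = ReactionTable(default_reactions(
            self.config.chemistry.include_phosphate))
        events = run_chemistry(
            ds2, index, self._rng("chem"), cfg, reactions,
            include_phosphate=self.config.chemistry.include_phosphate)
        events.to_csv(self.path("chem_events.csv"), index=False)
        return events

    def stage_indirect(self):
        events = _read_csv(self.path("chem_events.csv"), EVENT_COLUMNS)
        sbs = score_indirect_breaks(events, self._rng("indirect"),
                                    self.config.chemistry.p_indirect)
        sbs.to_csv(self.path("sb_indirect.csv"), index=False)
        return sbs

    def stage_score(self):
        """Per-event clustering, fragment analysis and PFGE filtering."""
        model, _ = self._load_model()
        sc = self.config.scoring
        sb_d = _read_csv(self.path("sb_direct.csv"), SB_COLUMNS)
        sb_i = _read_csv(self.path("sb_indirect.csv"), SB_COLUMNS)
        sbs = pd.concat([sb_d, sb_i], ignore_index=True)
        with open(self.path("run_meta.json")) as fh:
            n_events = json.load(fh)["n_events"]
        lengths = model.chromosome_lengths()

        rows, cluster_frames, fragment_frames = [], [], []
        for track_id in range(n_events):
            ev_sbs = dedupe_breaks(sbs[sbs["track_id"] == track_id],
                                   per_event=False)
            clusters = cluster_breaks(ev_sbs, sc.cluster_distance_bp)
            dsb = [c for c in clusters if c.classification == "DSB"]
            fragments = compute_fragments(dsb, lengths, sc.cut_position)
            _, distant = apply_detection_threshold(
                fragments, sc.min_fragment_bp, sc.distant_mode)
            tab = clusters_table(clusters)
            tab.insert(0, "track_id", track_id)
            cluster_frames.append(tab)
            frag = fragments[fragments["length"] >= sc.min_fragment_bp].copy()
            frag.insert(0, "track_id", track_id)
            fragment_frames.append(frag)
            rows.append(dict(
                track_id=track_id, n_dsb=len(dsb), n_distant=distant,
                n_complex_ssb=sum(c.classification == "complex_SSB"
                                  for c in clusters),
                n_simple_ssb=sum(c.classification == "simple_SSB"
                                 for c in clusters),
                n_sb_direct=int((ev_sbs["origin"] == "direct").sum()),
                n_sb_indirect=int((ev_sbs["origin"] == "indirect").sum())))
        counts = pd.DataFrame(rows)
        counts.to_csv(self.path("event_counts.csv"), index=False)
        pd.concat(cluster_frames, ignore_index=True).to_csv(
            self.path("clusters.csv"), index=False)
        pd.concat(fragment_frames, ignore_index=True).to_csv(
            self.path("fragments.csv"), index=False)
        return counts

    def stage_yield(self) -> YieldResult:
        counts = _read_csv(self.path("event_counts.csv"), ["track_id"])
        src = self._source()
        params = YieldParams(let_keV_per_um=src.let_kev_per_um)
        dist = counts["n_distant"].to_numpy(dtype=float)
        mean = float(dist.mean()) if len(dist) else 0.0
        se = (float(dist.std(ddof=1) / np.sqrt(len(dist)))
              if len(dist) > 1 else 0.0)
        complexity = {}
        try:
            cl = _read_csv(self.path("clusters.csv"), ["classification"])
            dsb_cl = cl[cl["classification"] == "DSB"]
            complexity = {int(k): int(v) for k, v in
                          dsb_cl["complexity"].value_counts().sort_index()
                          .items()}
        except FileNotFoundError:
            pass
        result = YieldResult(
            n_dsb_per_event=mean, se_per_event=se,
            n_dsb_gy_gbp=dsb_yield_normalization(mean, params),
            n_events=int(len(dist)), n_batches=1, converged=False,
            batch_means=[mean],
            breakdown=dict(
                n_dsb_total=int(counts["n_dsb"].sum()),
                n_distant_total=int(counts["n_distant"].sum()),
                n_sb_direct=int(counts["n_sb_direct"].sum()),
                n_sb_indirect=int(counts["n_sb_indirect"].sum()),
                n_complex_ssb=int(counts["n_complex_ssb"].sum()),
                n_simple_ssb=int(counts["n_simple_ssb"].sum()),
                dsb_complexity=complexity))
        write_report(result, self.config, self.path("result.json"))
        return result

    # -- drivers ------------------------------------------------------------

    def run(self, stages=STAGES) -> YieldResult | None:
        result = None
        for stage in stages:
            if stage not in STAGES:
                raise ConfigurationError(f"unknown stage {stage!r}")
            try:
                result = getattr(self, f"stage_{stage}")()
            except DnaDamageError:
                raise
            except Exception as exc:
                raise DnaDamageError(
                    f"stage {stage!r} failed: {exc}") from exc
        return result


def run_pipeline(config: RunConfig, output_dir=None) -> YieldResult:
    """Run every stage in order; returns the final yield result."""
    return Pipeline(config, output_dir).run()


def write_report(result: YieldResult, config: RunConfig, path) -> None:
    """Deterministic JSON report plus a short human-readable summary."""
    path = Path(path)
    payload = dict(result=result.to_dict(),
                   config=config.model_dump(),
                   config_hash=config.config_hash(),
                   seed=config.seed,
                   version=__version__)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
    lines = [
        "dnadamage run summary",
        f"  seed           : {config.seed}",
        f"  config hash    : {config.config_hash()}",
        f"  events         : {result.n_events}",
        f"  DSB/event      : {result.n_dsb_per_event:.4f}"
        f" +- {result.se_per_event:.4f}",
        f"  DSB/Gy/Gbp     : {result.n_dsb_gy_gbp:.4f}",
        f"  SB direct      : {result.breakdown.get('n_sb_direct', 0)}",
        f"  SB indirect    : {result.breakdown.get('n_sb_indirect', 0)}",
    ]
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def load_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def sweep_criteria(config: RunConfig, output_dir,
                   criteria: dict[str, dict]) -> dict[str, YieldResult]:
    """Rerun direct..yield for several direct-SB criteria.

    The upstream datasets (geometry, dataset 1/2, chemistry log) are
    produced once and shared; each criterion gets its own scoring subrun.
    """
    base = Pipeline(config, output_dir)
    base.run(("geometry", "irradiate", "chem"))
    results = {}
    for name, overrides in criteria.items():
        sub = Path(output_dir) / f"criterion_{name}"
        sub.mkdir(parents=True, exist_ok=True)
        for fname in ("geometry.txt", "dataset1_dna_deposits.csv",
                      "dataset2_radiolysis.csv", "chem_events.csv",
                      "run_meta.json"):
            (sub / fname).write_bytes(base.path(fname).read_bytes())
        cfg = config.model_copy(deep=True)
        for key, val in overrides.items():
            setattr(cfg.direct, key, val)
        pipe = Pipeline(cfg, sub)
        results[name] = pipe.run(("direct", "indirect", "score", "yield"))
    return results
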