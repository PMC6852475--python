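"""End-to-end orchestration: simulate/ingest -> preprocess -> localize ->
connectivity -> group stats -> NMF modules -> clinical correlates.

Every stage reads and writes the delimited formats in :mod:`srcconn.io`
under one output directory, records checksums in a run manifest, and is
skipped on re-run when its outputs already exist under the same config
hash.  Per-stage, per-subject seeds derive deterministically from the
master seed.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .beamform import LcmvBeamformer
from .clinical import correlation_table, network_summary, test_correlation
from .connectivity import aec_matrix, band_power, icoh_matrix, node_strength
from .containers import CANONICAL_BANDS, BandDefinition
from .nmf import (EnsembleNMF, module_map, select_edges, select_rank_bic,
                  test_module_weights)
from .preprocess import PreprocessConfig, preprocess
from .simulate import (PlantedEffect, SimulationConfig, inject_artifacts,
                       make_leadfield, mix_to_sensors, simulate_sources)
from .stats import (EmpiricalBayes, edge_features, pool_band_power,
                    pool_node_strength, results_table)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Single structured config driving every stage.

    Statistical defaults follow the study protocol where one is stated
    (edge/feature FDR q = 0.10, NMF edge screen alpha = 0.05, adaptive FDR
    q = 0.05); ensemble and resampling counts default to desk scale and
    ``protocol_scale=True`` restores the protocol values (10,000 bootstrap
    draws, 250 resamples, 100 restarts).
    """

    out_dir: str = "srcconn-out"
    seed: int = 0
    # simulation block (ignored when roi_input/sensor_input given)
    n_per_group: int = 10
    n_rois: int = 90
    n_sensors: int = 128
    fs: float = 512.0
    duration: float = 120.0
    n_blocks: int = 3
    sensor_snr: float = 5.0
    artifact_fraction: float = 0.0
    planted_effects: list = field(default_factory=list)  # dicts, see docs
    simulate_sensors: bool = True
    # optional external inputs (directories of io.write_timeseries files)
    roi_input: str | None = None
    sensor_input: str | None = None
    metadata: str | None = None
    # bands: list of [name, lo, hi]
    bands: list = field(default_factory=lambda: [
        [b.name, b.lo, b.hi] for b in CANONICAL_BANDS])
    # preprocessing
    z_threshold: float = 4.0
    bandpass: list = field(default_factory=lambda: [1.0, 97.0])
    notch: list = field(default_factory=lambda: [49.0, 51.0])
    # beamformer
    reg_fraction: float = 0.05
    # connectivity
    measures: list = field(default_factory=lambda: ["AEC", "iCoh"])
    epoch_seconds: float = 2.0
    # statistics
    q_fdr: float = 0.10
    nmf_alpha: float = 0.05
    afdr_q: float = 0.05
    n_perm: int = 500
    n_boot: int = 2000
    n_resamples: int = 50
    n_restarts: int = 20
    k_candidates: list = field(default_factory=lambda: [1, 2, 3])
    protocol_scale: bool = False

    def __post_init__(self) -> None:
        for spec_ in self.bands:
            BandDefinition(str(spec_[0]), float(spec_[1]), float(spec_[2]))
        if self.protocol_scale:
            self.n_boot = 10_000
            self.n_resamples = 250
            self.n_restarts = 100

    @property
    def band_defs(self) -> tuple[BandDefinition, ...]:
        return tuple(BandDefinition(str(n), float(lo), float(hi))
                     for n, lo, hi in self.bands)

    def effect_objects(self) -> tuple[PlantedEffect, ...]:
        by_name = {b.name: b for b in self.band_defs}
        out = []
        for d in self.planted_effects:
            d = dict(d)
            band = by_name[d.pop("band")]
            rois = tuple(int(r) for r in d.pop("rois"))
            out.append(PlantedEffect(band=band, rois=rois, **d))
        return tuple(out)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(master: int, *keys) -> int:
    """Deterministic per-stage / per-subject child seed below 2^31."""
    mix = [int(master)] + [zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence(mix).generate_state(1)[0] % (2 ** 31))


class Manifest:
    """Config hash, seeds and per-file checksums of a pipeline run."""

    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.path = out_dir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
            if self.data.get("config_hash") != config.hash():
                self.data = self._fresh(config)  # config changed: invalidate
        else:
            self.data = self._fresh(config)

    @staticmethod
    def _fresh(config: PipelineConfig) -> dict:
        return {"config_hash": config.hash(), "version": __version__,
                "seed": config.seed, "stages": {}, "files": {}}

    def stage_done(self, stage: str) -> bool:
        return stage in self.data["stages"]

    def record(self, stage: str, files: list[Path]) -> None:
        for f in files:
            digest = hashlib.sha256(Path(f).read_bytes()).hexdigest()
            self.data["files"][str(f)] = digest
        self.data["stages"][stage] = {"time": time.time(),
                                      "n_files": len(files)}
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=1))


class Pipeline:
    """Stage runner bound to one config and output directory."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = Manifest(self.out, config)

    # -- helpers ---------------------------------------------------------
    def _groups_table(self) -> pd.DataFrame:
        return pd.read_csv(self.out / "groups.csv")

    def _new_files(self, stage, produced) -> None:
        self.manifest.record(stage, [p for p in produced if Path(p).exists()])

    # -- stages ----------------------------------------------------------
    def simulate(self) -> None:
        if self.manifest.stage_done("simulate"):
            return
        cfg = self.cfg
        sim = SimulationConfig(
            n_per_group=cfg.n_per_group, n_rois=cfg.n_rois,
            n_sensors=cfg.n_sensors, fs=cfg.fs, duration=cfg.duration,
            n_blocks=cfg.n_blocks, bands=cfg.band_defs,
            planted_effects=cfg.effect_objects(), sensor_snr=cfg.sensor_snr,
            seed=derive_seed(cfg.seed, "simulate"))
        sources, truth = simulate_sources(sim)
        produced = []
        for roi_set in sources:
            p = self.out / "roi" / f"{roi_set.subject}.csv"
            io.write_timeseries(roi_set, p)
            produced += [p, p.with_suffix(".json")]
        if cfg.simulate_sensors:
            lf = make_leadfield(cfg.n_sensors, cfg.n_rois,
                                seed=derive_seed(cfg.seed, "leadfield"))
            io.write_leadfield(lf, self.out / "leadfield.csv")
            produced += [self.out / "leadfield.csv"]
            for roi_set in sources:
                sens = mix_to_sensors(
                    roi_set, lf, snr=cfg.sensor_snr,
                    seed=derive_seed(cfg.seed, "mix", roi_set.subject))
                if cfg.artifact_fraction > 0:
                    sens, _ = inject_artifacts(
                        sens, cfg.artifact_fraction,
                        seed=derive_seed(cfg.seed, "artifact", sens.subject))
                p = self.out / "sensor" / f"{sens.subject}.csv"
                io.write_timeseries(sens, p)
                produced += [p, p.with_suffix(".json")]
        io.write_ground_truth(truth, self.out / "truth.csv")
        groups = pd.DataFrame({"subject": truth.subject_ids,
                               "group": truth.groups})
        groups.to_csv(self.out / "groups.csv", index=False)
        self._new_files("simulate",
                        produced + [self.out / "truth.csv",
                                    self.out / "groups.csv"])

    def preprocess(self) -> None:
        if self.manifest.stage_done("preprocess"):
            return
        sensor_dir = Path(self.cfg.sensor_input or self.out / "sensor")
        if not sensor_dir.exists():
            return  # ROI-level input: nothing to do
        pcfg = PreprocessConfig(bandpass=tuple(self.cfg.bandpass),
                                notch=None if self.cfg.notch is None
                                else tuple(self.cfg.notch),
                                z_threshold=self.cfg.z_threshold)
        produced, reports = [], []
        for f in sorted(sensor_dir.glob("*.csv")):
            ts = io.read_timeseries(f)
            try:
                clean, report = preprocess(ts, pcfg)
            except ValueError as err:
                raise RuntimeError(
                    f"preprocess failed for subject {ts.subject}: {err}"
                ) from err
            p = self.out / "clean" / f.name
            io.write_timeseries(clean, p)
            produced += [p, p.with_suffix(".json")]
            reports.append({"subject": ts.subject,
                            "percent_rejected": report.percent_rejected})
        rp = self.out / "rejection_report.csv"
        pd.DataFrame(reports).to_csv(rp, index=False)
        self._new_files("preprocess", produced + [rp])

    def localize(self) -> None:
        if self.manifest.stage_done("localize"):
            return
        roi_dir = Path(self.cfg.roi_input or self.out / "roi")
        clean_dir = self.out / "clean"
        if roi_dir.exists() and not clean_dir.exists():
            return  # bypass: ROI series provided directly
        if not clean_dir.exists():
            raise RuntimeError("localize: no cleaned sensor data found")
        lf = io.read_leadfield(self.out / "leadfield.csv")
        produced = []
        for f in sorted(clean_dir.glob("*.csv")):
            ts = io.read_timeseries(f)
            try:
                roi_set = LcmvBeamformer(
                    lf, reg_fraction=self.cfg.reg_fraction).fit_transform(ts)
            except ValueError as err:
                raise RuntimeError(
                    f"localize failed for subject {ts.subject}: {err}"
                ) from err
            p = self.out / "roi_beamformed" / f.name
            io.write_timeseries(roi_set, p)
            produced += [p, p.with_suffix(".json")]
        self._new_files("localize", produced)

    def _roi_sets(self):
        for d in ("roi_beamformed", None):
            roi_dir = (self.out / d) if d else \
                Path(self.cfg.roi_input or self.out / "roi")
            if roi_dir.exists():
                return [io.read_timeseries(f)
                        for f in sorted(roi_dir.glob("*.csv"))]
        raise RuntimeError("no ROI time series available")

    def connectivity(self) -> None:
        if self.manifest.stage_done("connectivity"):
            return
        produced = []
        for roi_set in self._roi_sets():
            sid = roi_set.subject
            mats = []
            if "AEC" in self.cfg.measures:
                mats += [aec_matrix(roi_set, b) for b in self.cfg.band_defs]
            if "iCoh" in self.cfg.measures:
                mats += icoh_matrix(roi_set, self.cfg.band_defs,
                                    epoch_seconds=self.cfg.epoch_seconds)
            for m in mats:
                p = self.out / "connectivity" / \
                    f"{sid}__{m.measure}__{m.band.name}.csv"
                io.write_matrix(m, p)
                produced += [p, p.with_suffix(".json")]
            bp = band_power(roi_set, self.cfg.band_defs,
                            epoch_seconds=self.cfg.epoch_seconds)
            p = self.out / "power" / f"{sid}.csv"
            p.parent.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(bp.values, index=bp.labels,
                         columns=[b.name for b in bp.bands]).to_csv(p)
            produced.append(p)
        self._new_files("connectivity", produced)

    def _load_matrices(self, measure, band_name):
        files = sorted((self.out / "connectivity")
                       .glob(f"*__{measure}__{band_name}.csv"))
        return [io.read_matrix(f) for f in files]

    def stats(self) -> None:
        if self.manifest.stage_done("stats"):
            return
        cfg = self.cfg
        groups_df = self._groups_table()
        groups = groups_df["group"].to_numpy()
        produced, summaries = [], []
        stat_dir = self.out / "stats"
        stat_dir.mkdir(parents=True, exist_ok=True)

        def run_ebi(fm, name, seed_key):
            eb = EmpiricalBayes(q=cfg.q_fdr, n_perm=cfg.n_perm,
                                seed=derive_seed(cfg.seed, "stats", seed_key))
            eb.fit(fm.values, np.asarray(fm.groups))
            tbl = results_table(fm, eb.result_)
            p = stat_dir / f"{name}_results.csv"
            tbl.to_csv(p, index=False)
            produced.append(p)
            summaries.append({"run": name, "pi0": eb.pi0_,
                              "power": eb.power_, "q": cfg.q_fdr,
                              "n_significant": int(eb.mask_.sum()),
                              "threshold": eb.result_.threshold})

        # spectral power: concatenated across bands
        power_files = sorted((self.out / "power").glob("*.csv"))
        from .containers import BandPower
        powers = []
        for f in power_files:
            df = pd.read_csv(f, index_col=0)
            powers.append(BandPower(subject=f.stem,
                                    values=df.to_numpy(float),
                                    bands=cfg.band_defs,
                                    labels=list(df.index)))
        run_ebi(pool_band_power(powers, groups), "power", "power")

        # node strength: concatenated across bands per measure
        for measure in cfg.measures:
            strengths = {}
            for b in cfg.band_defs:
                mats = self._load_matrices(measure, b.name)
                strengths[b.name] = [node_strength(m) for m in mats]
            fm = pool_node_strength(strengths, groups, measure)
            run_ebi(fm, f"{measure}_strength", f"{measure}-strength")

        # point-to-point edges: one run per (measure, band)
        for measure in cfg.measures:
            for b in cfg.band_defs:
                mats = self._load_matrices(measure, b.name)
                fm = edge_features(mats, groups)
                run_ebi(fm, f"{measure}_edges_{b.name}",
                        f"{measure}-{b.name}")
        p = stat_dir / "summary.csv"
        pd.DataFrame(summaries).to_csv(p, index=False)
        self._new_files("stats", produced + [p])

    def nmf(self) -> None:
        if self.manifest.stage_done("nmf"):
            return
        cfg = self.cfg
        groups = self._groups_table()["group"].to_numpy()
        produced = []
        nmf_dir = self.out / "nmf"
        nmf_dir.mkdir(parents=True, exist_ok=True)
        for measure in cfg.measures:
            for b in cfg.band_defs:
                mats = self._load_matrices(measure, b.name)
                sel = select_edges(mats, groups, alpha=cfg.nmf_alpha)
                tag = f"{measure}__{b.name}"
                if sel.edges.shape[0] < max(cfg.k_candidates):
                    (nmf_dir / f"{tag}__SKIPPED.txt").write_text(
                        f"only {sel.edges.shape[0]} discriminant edges; "
                        "NMF skipped\n")
                    produced.append(nmf_dir / f"{tag}__SKIPPED.txt")
                    continue
                seed = derive_seed(cfg.seed, "nmf", tag)
                k, bic = select_rank_bic(sel.v, cfg.k_candidates,
                                         n_restarts=cfg.n_restarts, seed=seed)
                model = EnsembleNMF(k=k, n_resamples=cfg.n_resamples,
                                    n_restarts=cfg.n_restarts,
                                    seed=seed).fit(sel.v, groups)
                maps = module_map(model, edges=sel.edges)
                rows = [{"measure": measure, "band": b.name,
                         "module": mm.module, "roi_i": int(e[0]),
                         "roi_j": int(e[1]), "score": mm.scores[k2],
                         "sign": mm.sign}
                        for mm in maps
                        for k2, e in enumerate(sel.edges)]
                paths = {
                    "modules": pd.DataFrame(rows),
                    "weights": pd.DataFrame(
                        model.W_,
                        columns=[f"module_{i}" for i in range(k)]),
                    "bic": pd.DataFrame(sorted(bic.items()),
                                        columns=["k", "bic"]),
                    "module_tests": test_module_weights(
                        model, n_boot=cfg.n_boot, q=cfg.afdr_q,
                        seed=derive_seed(cfg.seed, "nmf-test", tag)),
                }
                for name, df in paths.items():
                    p = nmf_dir / f"{tag}__{name}.csv"
                    df.to_csv(p, index=False)
                    produced.append(p)
        self._new_files("nmf", produced)

    def clinical(self) -> None:
        if self.manifest.stage_done("clinical"):
            return
        cfg = self.cfg
        meta_path = cfg.metadata or (self.out / "metadata.csv")
        if not Path(meta_path).exists():
            return  # clinical covariates not supplied
        meta = pd.read_csv(meta_path).set_index("subject")
        groups_df = self._groups_table()
        patient_level = sorted(groups_df["group"].unique())[-1]
        patients = groups_df[groups_df["group"] == patient_level]["subject"]
        rows = []
        seed = derive_seed(cfg.seed, "clinical")
        pairs = [("motor", "iCoh", "beta", "alsfrs_r", True),
                 ("motor", "iCoh", "beta", "motor_volume", True),
                 ("frontal", "iCoh", "delta", "frontal_volume", True)]
        for net, measure, band_name, target, partial in pairs:
            mats = {m.subject: m
                    for m in self._load_matrices(measure, band_name)}
            sub = [s for s in patients
                   if s in mats and s in meta.index
                   and np.isfinite(meta.loc[s].get(target, np.nan))]
            if len(sub) < 6:
                continue
            x = np.array([network_summary(mats[s], net) for s in sub])
            y = meta.loc[sub, target].to_numpy(float)
            z = meta.loc[sub, "age"].to_numpy(float) if partial else None
            rho, p, power = test_correlation(x, y, z, n_boot=cfg.n_boot,
                                             seed=seed)
            rows.append({"network": net, "measure": measure,
                         "band": band_name, "target": target,
                         "method": "spearman_partial(age)" if partial
                         else "spearman",
                         "rho": rho, "p": p, "power": power, "n": len(sub)})
        out = self.out / "clinical_correlations.csv"
        correlation_table(rows).to_csv(out, index=False)
        self._new_files("clinical", [out])

    def report(self) -> None:
        rep_dir = self.out / "report"
        rep_dir.mkdir(parents=True, exist_ok=True)
        sections = {
            "stats_summary": self.out / "stats" / "summary.csv",
            "clinical": self.out / "clinical_correlations.csv",
            "rejection": self.out / "rejection_report.csv",
        }
        lines = []
        for name, src in sections.items():
            if src.exists():
                dst = rep_dir / src.name
                dst.write_text(src.read_text())
                lines.append(f"{name}: {dst.name}")
            else:
                lines.append(f"{name}: ABSENT")
        sig = []
        stats_dir = self.out / "stats"
        if stats_dir.exists():
            for f in sorted(stats_dir.glob("*_results.csv")):
                df = pd.read_csv(f)
                sig.append(df[df["significant"]]
                           .assign(run=f.stem.replace("_results", "")))
        if sig:
            pd.concat(sig, ignore_index=True).to_csv(
                rep_dir / "significant_features.csv", index=False)
            lines.append("significant_features: significant_features.csv")
        else:
            lines.append("significant_features: ABSENT")
        nmf_dir = self.out / "nmf"
        if nmf_dir.exists() and any(nmf_dir.glob("*__modules.csv")):
            pd.concat([pd.read_csv(f)
                       for f in sorted(nmf_dir.glob("*__modules.csv"))],
                      ignore_index=True).to_csv(rep_dir / "module_maps.csv",
                                                index=False)
            lines.append("module_maps: module_maps.csv")
        else:
            lines.append("module_maps: ABSENT")
        (rep_dir / "README.txt").write_text("\n".join(lines) + "\n")

    def run(self) -> None:
        if self.cfg.roi_input is None and self.cfg.sensor_input is None:
            self.simulate()
        self.preprocess()
        self.localize()
        self.connectivity()
        self.stats()
        self.nmf()
        self.clinical()
        self.report()
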