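"""End-to-end analysis pipeline.

Synthetic fixture (or user topology + trajectory) → distance features →
TICA → free-energy surface → k-means microstates → reversible MSM →
implied-timescale macrostate selection → PCCA+ → MFPTs → pathway/trap
decomposition → per-macrostate contact persistence, constriction widths and
the mutation report. Every stage is seeded and the run manifest records
parameters, seeds and output checksums, so reruns are bit-identical.

Trajectory ensembles are processed in two streaming passes (covariance
accumulation, then projection), so only one trajectory's coordinates are
ever held in memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as contacts_mod
from . import geometry as geometry_mod
from . import msm as msm_mod
from . import mutations as mutations_mod
from . import synthetic
from . import tica as tica_mod
from .formats_io import (Topology, Trajectory, annotate_domains,
                         read_multimodel_trajectory, read_pdb_topology)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated stage parameters for one analysis run."""

    system: str | None = "xpd"          # synthetic fixture name, or None
    topology_path: str | None = None    # user-input mode
    trajectory_path: str | None = None
    frame_interval_ps: float = 1e6      # 1 µs fixture frame interval
    domain_ranges: list = field(default_factory=list)

    n_traj: int = 60
    n_frames: int = 5000
    sigma: float = 0.3                  # Å emission noise

    stride: int = 6                     # Cα stride for distance features
    include_dna: bool = True
    tica_lag: int = 5                   # frames
    n_ics: int = 10

    k: int = 200                        # microstates (reduced from 1500)
    msm_lag: int = 3                    # frames
    n_macrostates: int | None = None    # None = implied-timescale gap rule
    max_macrostates: int = 12

    fes_bins: int = 60
    contact_sample: int = 120           # frames per macrostate for contacts
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.system is None and (self.topology_path is None
                                    or self.trajectory_path is None):
            raise ValueError("either a synthetic system or topology+trajectory "
                             "paths are required")
        if self.system is not None and self.system not in ("xpd", "ding"):
            raise ValueError(f"unknown synthetic system {self.system!r}")
        for name in ("n_traj", "n_frames", "stride", "tica_lag", "n_ics", "k",
                     "msm_lag", "max_macrostates", "fes_bins", "contact_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_traj * self.n_frames < self.k:
            raise ValueError("k exceeds the total number of frames")
        if self.n_frames <= max(self.tica_lag, self.msm_lag):
            raise ValueError("trajectories shorter than the lag time")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        profile = data.pop("profile", None)
        base = dict(PROFILES[profile]) if profile else {}
        base.update(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(base) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**base)


#: paper-defaults profiles; sampling sizes are the desk-scale study
#: conditions (the full-scale parameters are k=1500 microstates at a
#: 1500 ps lag on 6 µs of aggregate sampling)
PROFILES = {
    "xpd_paper": dict(system="xpd", n_traj=60, n_frames=5000, sigma=0.3,
                      stride=6, include_dna=True, tica_lag=5, n_ics=10,
                      k=200, msm_lag=3, n_macrostates=None, max_macrostates=12),
    "ding_paper": dict(system="ding", n_traj=60, n_frames=5000, sigma=0.3,
                       stride=6, include_dna=True, tica_lag=5, n_ics=10,
                       k=200, msm_lag=3, n_macrostates=None, max_macrostates=12),
}


@dataclass
class PipelineResult:
    config: PipelineConfig
    fixture: synthetic.KineticFixture | None
    topology: Topology
    feature_spec: tica_mod.FeatureSpec
    tica_model: tica_mod.TICAModel
    fes: tica_mod.FESGrid
    micro: msm_mod.MicrostateModel
    tmatrix: msm_mod.TransitionMatrix
    its: msm_mod.ImpliedTimescales
    macro: msm_mod.MacrostateModel
    mfpt: msm_mod.MFPTMatrix
    pathway: msm_mod.PathwayDecomposition | None
    micro_labels: list[np.ndarray]
    macro_labels: list[np.ndarray]
    true_state_seqs: list[np.ndarray] | None
    endpoint_macros: tuple[int, int] | None
    contact_table: contacts_mod.ContactTable
    widths: pd.DataFrame
    mutation_report: pd.DataFrame | None
    manifest: dict

    @property
    def n_macrostates(self) -> int:
        return self.macro.m

    def assign_frames(self, coords: np.ndarray) -> np.ndarray:
        """Project raw frames and assign them to macrostates via the MSM."""
        fm = tica_mod.compute_features(np.asarray(coords), self.feature_spec)
        Y = tica_mod.project(self.tica_model, fm)
        micro = self.micro.assign(Y)
        return self._micro_to_macro(micro)

    def _micro_to_macro(self, micro: np.ndarray) -> np.ndarray:
        active = self.tmatrix.active
        crisp = np.full(self.micro.k, -1, dtype=int)
        crisp[active] = self.macro.crisp
        return crisp[micro]

    def template_macrostate(self, state_id: str) -> int:
        """Macrostate index a fixture template maps to."""
        if self.fixture is None:
            raise ValueError("no fixture attached")
        t = self.fixture.states[self.fixture.index(state_id)].coordinates
        return int(self.assign_frames(t[None])[0])


def _traj_seed(base_seed: int, i: int) -> int:
    return (base_seed * 100_003 + 7919 * i + 1) % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    t_start = time.time()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------ input stage
    if config.system is not None:
        builder = (synthetic.build_xpd_fixture if config.system == "xpd"
                   else synthetic.build_ding_fixture)
        topology, fixture = builder()
        log.info("stage input: %s fixture, %d trajectories × %d frames, σ=%.2f Å",
                 config.system, config.n_traj, config.n_frames, config.sigma)
        seqs = synthetic.simulate_ensemble(fixture, config.n_traj,
                                           config.n_frames, config.seed)

        def traj_iter():
            for i, seq in enumerate(seqs):
                em = synthetic.EmissionModel(config.sigma,
                                             _traj_seed(config.seed, i))
                yield synthetic.emit_trajectory(seq, fixture, em).coordinates
    else:
        fixture = None
        seqs = None
        topology = read_pdb_topology(config.topology_path)
        if config.domain_ranges:
            topology = annotate_domains(
                topology, [tuple(r) for r in config.domain_ranges])
        user_traj = read_multimodel_trajectory(config.trajectory_path, topology,
                                               config.frame_interval_ps)

        def traj_iter():
            yield user_traj.coordinates

    # ------------------------------------------------------ features and TICA
    spec = tica_mod.build_feature_spec(topology, stride=config.stride,
                                       include_dna=config.include_dna)
    log.info("stage features: %d distance pairs (stride %d, include_dna=%s)",
             spec.n_features, config.stride, config.include_dna)
    acc = tica_mod.CovarianceAccumulator(spec.n_features, config.tica_lag)
    n_list = []
    sample = None
    for coords in traj_iter():
        X = tica_mod.compute_features(coords, spec).values
        if sample is None:
            sample = X[:100]
        acc.add(X)
        n_list.append(X.shape[0])
    variances = np.var(sample, axis=0)
    kept = np.where(variances > 1e-12)[0]
    mean, C0, Ct = _finalize_subset(acc, kept)
    model = tica_mod._solve_tica(mean, C0, Ct, config.n_ics)
    model.lag = config.tica_lag
    model.kept_columns = kept
    log.info("stage tica: eigenvalues %s", np.round(model.eigenvalues[:4], 4))

    projections = []
    for coords in traj_iter():
        X = tica_mod.compute_features(coords, spec).values
        projections.append(tica_mod.project(model, X))
    Y_all = np.concatenate(projections)
    fes = tica_mod.free_energy_surface(Y_all[:, :2], bins=config.fes_bins)

    # --------------------------------------------------------------------- MSM
    micro = msm_mod.kmeans_cluster(Y_all, config.k, seed=config.seed)
    micro_labels = []
    off = 0
    for n in n_list:
        micro_labels.append(micro.labels[off:off + n])
        off += n
    counts = msm_mod.count_matrix(micro_labels, config.msm_lag,
                                  n_states=config.k)
    tmatrix = msm_mod.estimate_reversible_T(counts)
    dt_s = (fixture.dt_seconds if fixture is not None
            else config.frame_interval_ps * 1e-12)
    its = msm_mod.implied_timescales(tmatrix, config.msm_lag, dt_s)
    if config.n_macrostates is None:
        m = msm_mod.select_n_macrostates(its, config.max_macrostates)
    else:
        m = config.n_macrostates
    log.info("stage msm: %d active microstates, m=%d macrostates",
             tmatrix.n_states, m)
    macro = msm_mod.pcca_coarse_grain(tmatrix, m)
    mfpt = msm_mod.mfpt_and_rates(macro, config.msm_lag, dt_s)

    result_labels = []
    active = tmatrix.active
    crisp_full = np.full(config.k, -1, dtype=int)
    crisp_full[active] = macro.crisp
    for lab in micro_labels:
        result_labels.append(crisp_full[lab])

    # pathway decomposition between the fixture's cycle endpoints
    pathway = None
    endpoints = None
    if fixture is not None:
        res_stub = PipelineResult(
            config=config, fixture=fixture, topology=topology,
            feature_spec=spec, tica_model=model, fes=fes, micro=micro,
            tmatrix=tmatrix, its=its, macro=macro, mfpt=mfpt, pathway=None,
            micro_labels=micro_labels, macro_labels=result_labels,
            true_state_seqs=seqs, endpoint_macros=None,
            contact_table=None, widths=None, mutation_report=None, manifest={})
        source = res_stub.template_macrostate(fixture.on_path[0])
        sink = res_stub.template_macrostate(fixture.on_path[-1])
        endpoints = (source, sink)
        if source >= 0 and sink >= 0 and source != sink:
            pathway = msm_mod.decompose_pathway(macro, source, sink)
        else:
            log.warning("cycle endpoints not resolved as distinct macrostates "
                        "(%s); skipping pathway decomposition", endpoints)

    # --------------------------------------------- contacts, widths, mutations
    table, widths = _contacts_and_widths(config, topology, fixture, seqs,
                                         result_labels)
    report = None
    if fixture is not None and fixture.name == "xpd":
        report = mutations_mod.mutation_report(mutations_mod.build_catalog(),
                                               table, topology)

    manifest = _manifest(config, spec, its, macro, endpoints, t_start)
    result = PipelineResult(
        config=config, fixture=fixture, topology=topology, feature_spec=spec,
        tica_model=model, fes=fes, micro=micro, tmatrix=tmatrix, its=its,
        macro=macro, mfpt=mfpt, pathway=pathway, micro_labels=micro_labels,
        macro_labels=result_labels, true_state_seqs=seqs,
        endpoint_macros=endpoints, contact_table=table, widths=widths,
        mutation_report=report, manifest=manifest)
    if out:
        _write_outputs(result, out)
    return result


def _finalize_subset(acc, kept):
    mean = (acc.sum / acc.n)[kept]
    C0 = acc.c00[np.ix_(kept, kept)] / acc.n - np.outer(mean, mean)
    Ct = acc.c0t[np.ix_(kept, kept)] / acc.n - np.outer(mean, mean)
    return mean, C0, Ct


def _contacts_and_widths(config, topology, fixture, seqs, macro_labels):
    """Subsampled per-macrostate contact persistence and channel widths."""
    rng = np.random.default_rng(config.seed + 17)
    flat = np.concatenate(macro_labels)
    states = np.unique(flat[flat >= 0])
    # pick (traj, frame) indices per macrostate
    chosen: dict[int, list[tuple[int, int]]] = {int(s): [] for s in states}
    for s in states:
        pool = []
        for i, lab in enumerate(macro_labels):
            idx = np.where(lab == s)[0]
            pool.extend((i, int(t)) for t in idx)
        take = min(config.contact_sample, len(pool))
        sel = rng.choice(len(pool), size=take, replace=False)
        chosen[int(s)] = [pool[j] for j in sel]
    by_traj: dict[int, list[tuple[int, int]]] = {}
    for s, lst in chosen.items():
        for i, t in lst:
            by_traj.setdefault(i, []).append((t, s))

    detector = contacts_mod.ContactDetector(topology)
    cdefs = (fixture.constrictions if fixture is not None else {})
    events, labels, widths_rows = [], [], []
    for i, frames in sorted(by_traj.items()):
        if fixture is not None:
            em = synthetic.EmissionModel(config.sigma, _traj_seed(config.seed, i))
            coords = synthetic.emit_trajectory(seqs[i], fixture, em).coordinates
        else:
            raise NotImplementedError("contact stage for user input uses the "
                                      "contacts module directly")
        for t, s in frames:
            frame = coords[t]
            events.append(detector.detect(frame, t))
            labels.append(s)
            for cname, cdef in cdefs.items():
                widths_rows.append(
                    (s, cname,
                     geometry_mod.constriction_width(frame, cdef, topology)))
    table = contacts_mod.persistence_table(events, np.asarray(labels),
                                           topology)
    wdf = pd.DataFrame(widths_rows, columns=["state", "constriction", "width"])
    widths = (wdf.groupby(["state", "constriction"])["width"]
              .agg(["mean", "std", "count"]).reset_index())
    return table, widths


def _manifest(config, spec, its, macro, endpoints, t_start) -> dict:
    return {
        "config": dataclasses.asdict(config),
        "n_features": int(spec.n_features),
        "timescales_s": [None if not np.isfinite(t) else float(t)
                         for t in its.timescales[:12]],
        "n_macrostates": int(macro.m),
        "endpoint_macrostates": endpoints,
        "wall_time_s": round(time.time() - t_start, 2),
        "versions": {"numpy": np.__version__},
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(result: PipelineResult, out: Path) -> None:
    tica_mod.write_fes(result.fes, out / "fes.txt")
    np.savetxt(out / "coarse_transition_matrix.csv", result.macro.coarse_T,
               delimiter=",", fmt="%.8g")
    np.savetxt(out / "pcca_memberships.csv", result.macro.chi,
               delimiter=",", fmt="%.8g")
    np.savetxt(out / "mfpt_seconds.csv", result.mfpt.mfpt,
               delimiter=",", fmt="%.8g")
    ts = pd.DataFrame({"timescale_s": result.its.timescales})
    ts.to_csv(out / "implied_timescales.csv", index=False)
    result.contact_table.to_frame().to_csv(out / "contacts.csv", index=False)
    result.widths.to_csv(out / "widths.csv", index=False)
    if result.mutation_report is not None:
        result.mutation_report.to_csv(out / "mutation_report.csv", index=False)
    if result.pathway is not None:
        (out / "pathway.json").write_text(json.dumps(
            {"on_path": result.pathway.on_path, "traps": result.pathway.traps,
             "endpoint_macrostates": result.endpoint_macros}))
    manifest = dict(result.manifest)
    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(out.iterdir())
                           if p.name != "manifest.json"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    result.manifest = manifest
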