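"""End-to-end session pipeline: states -> slow waves -> laminar map ->
units -> coupling -> connectivity, with serialized per-stage outputs.

A session lives in one directory::

    session/
      lfp.lfp (+ .json descriptor)     continuous LFP, geometric order
      wideband.dat (+ .json)           optional short wideband segment
      spikes/                          spikes.tsv, units.csv, waveforms.csv
      events.csv                       light pulses etc.
      ground_truth.json                present for synthetic sessions
      out/                             stage outputs (JSON / CSV)

Each stage reads upstream artifacts from ``out/`` and is idempotent; the
single session seed fans out to per-stage seeds through a seed sequence so
stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import io, laminar, spectral, states, units
from ._utils import spawn_seeds
from .io import ConfigurationError

STAGES = ("score_states", "detect_slowwaves", "laminar_map",
          "classify_units", "couple", "detect_connections")


class StageError(RuntimeError):
    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class SessionConfig:
    """Paths plus every tunable stage parameter (defaults as documented in
    the per-module docstrings).  Unknown keys are rejected on load."""

    session_dir: str = "."
    out_dir: str | None = None
    lfp_file: str = "lfp.lfp"
    wideband_file: str = "wideband.dat"
    spikes_dir: str = "spikes"
    events_file: str = "events.csv"
    seed: int = 0

    # state scoring
    scoring_channel: int | None = None
    min_wake_s: float = 420.0
    # slow waves
    sw_rate_criterion: float = 0.2
    sw_min_duration_s: float = 0.040
    # laminar
    gamma_band: tuple = (30.0, 100.0)
    cluster_restarts: int = 20
    n_pcs: int = 10
    n_ics: int = 6
    coherence_state: str = "WAKE"
    # units / coupling
    coupling_scales: int = 20
    k_range: tuple = (2, 12)
    # connectivity
    conn_min_spikes: int = 100
    conn_min_pre_spikes: int = 500

    def resolve(self) -> "SessionConfig":
        out = self.out_dir or str(Path(self.session_dir) / "out")
        return dataclasses.replace(self, out_dir=out)

    @classmethod
    def from_file(cls, path) -> "SessionConfig":
        d = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gamma_band", "k_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _paths(cfg: SessionConfig):
    cfg = cfg.resolve()
    root = Path(cfg.session_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return cfg, root, out


def _load_lfp(cfg, root):
    f = root / cfg.lfp_file
    if not f.exists():
        raise ConfigurationError(f"missing LFP file: {f}")
    return io.load_recording(f)


def _load_spikes(cfg, root):
    d = root / cfg.spikes_dir
    if not d.exists():
        raise ConfigurationError(f"missing spike directory: {d}")
    return io.load_spikes(d)


def _stage_seed(cfg, stage: str) -> int:
    return spawn_seeds(cfg.seed, len(STAGES))[STAGES.index(stage)]


# --------------------------------------------------------------------------
# stages


def stage_score_states(cfg: SessionConfig) -> states.StateSegmentation:
    cfg, root, out = _paths(cfg)
    rec = _load_lfp(cfg, root)
    traces = states.compute_scoring_traces(rec, channel=cfg.scoring_channel)
    seg = states.score_states(traces, min_wake_s=cfg.min_wake_s)
    io.save_intervals(seg.intervals, out / "states.csv")
    io.save_json({"merged_arousals": seg.merged_arousals}, out / "states_meta.json")
    return seg


def stage_detect_slowwaves(cfg: SessionConfig) -> states.DownUpEvents | None:
    cfg, root, out = _paths(cfg)
    f = out / "states.csv"
    if not f.exists():
        raise ConfigurationError(f"missing upstream state intervals: {f} "
                                 "(run score-states first)")
    seg_iv = io.load_intervals(f)
    nrem = [(s, e) for s, e, lab in seg_iv if lab == "NREM"]
    rows: list = []
    if sum(e - s for s, e in nrem) < 60:
        io.save_intervals(rows, out / "downup.csv")
        return None
    rec = _load_lfp(cfg, root)
    spikes = _load_spikes(cfg, root)
    ev = states.detect_slow_waves(rec, spikes, nrem,
                                  channel=cfg.scoring_channel,
                                  rate_criterion=cfg.sw_rate_criterion,
                                  min_duration_s=cfg.sw_min_duration_s)
    rows = [(s, e, "DOWN") for s, e in ev.down] + [(s, e, "UP") for s, e in ev.up]
    io.save_intervals(sorted(rows), out / "downup.csv")
    return ev


def stage_laminar_map(cfg: SessionConfig) -> laminar.LaminarMap:
    cfg, root, out = _paths(cfg)
    rec = _load_lfp(cfg, root)
    seed_c, seed_i = spawn_seeds(_stage_seed(cfg, "laminar_map"), 2)

    seg_f = out / "states.csv"
    state_iv = io.load_intervals(seg_f) if seg_f.exists() else []
    coh_iv = [(s, e) for s, e, lab in state_iv if lab == cfg.coherence_state]
    if sum(e - s for s, e in coh_iv) < 10:
        coh_iv = None

    C = spectral.band_coherence_matrix(rec, band=cfg.gamma_band,
                                       state_intervals=coh_iv)
    clustering = laminar.gradient_descent_cluster(C, n_restarts=cfg.cluster_restarts,
                                                  seed=seed_c)
    ica = laminar.gamma_ica(rec, band=cfg.gamma_band, n_pcs=cfg.n_pcs,
                            n_ics=cfg.n_ics, seed=seed_i, intervals=coh_iv)

    # landmarks: MUA profile (wideband if present, spiking-hash fallback)
    wb_f = root / cfg.wideband_file
    if wb_f.exists():
        profile = laminar.mua_power_profile(io.load_recording(wb_f))
    else:
        profile = laminar.mua_power_profile(
            rec, band=(100.0, min(400.0, 0.45 * rec.fs)))
    landmarks = None
    du_f = out / "downup.csv"
    if du_f.exists():
        transitions = [e for s, e, lab in io.load_intervals(du_f) if lab == "DOWN"]
        if len(transitions) >= 10:
            csd = laminar.event_triggered_csd(rec, np.asarray(transitions),
                                              trigger="DOWN-UP transition")
            try:
                landmarks = laminar.find_landmarks(profile, csd)
            except laminar.LandmarkError:
                landmarks = None
    warp = laminar.normalize_depth(landmarks, landmarks) if landmarks else None

    lmap = laminar.LaminarMap(
        landmark_depths_um=landmarks or {},
        warp=warp,
        cluster_of_channel=clustering.assignment,
        ic_loadings=ica.loadings[ica.laminar_ics],
        ic_relative_power=ica.relative_power[ica.laminar_ics],
    )
    io.save_json({
        "landmarks_um": landmarks or {},
        "cluster_of_channel": clustering.assignment,
        "n_clusters": clustering.n_clusters,
        "cluster_energy": clustering.energy,
        "cluster_consistency": clustering.consistency,
        "ic_loadings": ica.loadings[ica.laminar_ics],
        "ic_relative_power": ica.relative_power[ica.laminar_ics],
        "ic_uniform_flags": ica.is_uniform,
        "warp_knots": ([warp.knots_in, warp.knots_out] if warp else None),
    }, out / "laminar_map.json")
    # IC time courses are needed downstream (coupling); store as CSV
    ts = pd.DataFrame(ica.time_series[ica.laminar_ics].T)
    ts.to_csv(out / "ic_timeseries.csv.gz", index=False, float_format="%.5g",
              compression="gzip")
    return lmap


def stage_classify_units(cfg: SessionConfig) -> pd.DataFrame:
    cfg, root, out = _paths(cfg)
    spikes = _load_spikes(cfg, root)
    rec = _load_lfp(cfg, root)
    duration = rec.duration_s

    if spikes.waveforms:
        table = units.classify_units(spikes.waveforms, spikes.waveform_fs)
    else:
        table = pd.DataFrame(index=pd.Index(spikes.unit_ids, name="unit_id"))
        table["waveform_class"] = "UNKNOWN"
        table["tp_latency_ms"] = np.nan

    ev_f = root / cfg.events_file
    pulses = np.empty(0)
    if ev_f.exists():
        ev = io.load_events(ev_f)
        pulses = ev.loc[ev["type"] == "LIGHT_OPTO", "time_s"].to_numpy()
    state_iv = io.load_intervals(out / "states.csv") if (out / "states.csv").exists() else []
    du = io.load_intervals(out / "downup.csv") if (out / "downup.csv").exists() else []
    down_iv = [(s, e) for s, e, lab in du if lab == "DOWN"]
    up_iv = [(s, e) for s, e, lab in du if lab == "UP"]
    up_onsets = np.asarray([s for s, _ in up_iv])

    rows = []
    for uid in spikes.unit_ids:
        t = spikes.spike_times[uid]
        row = {"unit_id": uid, "n_spikes": t.size,
               "mean_rate_hz": t.size / duration}
        row["opto_tagged"] = False
        if pulses.size >= 100 and t.size:
            tagged, *_ = units.optotag(t, pulses)
            row["opto_tagged"] = bool(tagged)
        row["burst_index"] = (units.burst_index(t) if t.size >= 100 else np.nan)
        if state_iv:
            srt = units.state_rate_table(t, state_iv)
            for lab in srt.index:
                row[f"rate_{lab.lower()}_hz"] = srt.loc[lab, "rate_hz"]
            row["wake_nrem_ratio"] = srt.attrs["wake_nrem_ratio"]
        if up_onsets.size >= 50:
            ratio, latency = units.up_state_dynamics(t, up_onsets)
            row["transient_steady_ratio"] = ratio
            row["downup_latency_s"] = latency
        if len(down_iv) >= 50 and len(up_iv) >= 50:
            da = units.detect_down_active(t, down_iv, up_iv, unit_id=uid)
            row["down_active"] = da.flagged
            row["rate_down_hz"] = da.rate_down_hz
            row["rate_up_hz"] = da.rate_up_hz
        rows.append(row)
    stats_df = pd.DataFrame(rows).set_index("unit_id")
    merged = table.join(stats_df, how="outer")
    merged.to_csv(out / "units.csv")
    return merged


def stage_couple(cfg: SessionConfig):
    cfg, root, out = _paths(cfg)
    ts_f = out / "ic_timeseries.csv.gz"
    if not ts_f.exists():
        raise ConfigurationError(f"missing IC time series: {ts_f} "
                                 "(run laminar-map first)")
    ics = pd.read_csv(ts_f).to_numpy().T
    rec = _load_lfp(cfg, root)
    spikes = _load_spikes(cfg, root)
    trains = {u: spikes.spike_times[u] for u in spikes.unit_ids}
    R, F, P, uids = spectral.spike_phase_coupling_matrix(
        trains, ics, rec.fs, band=cfg.gamma_band, n_scales=cfg.coupling_scales)
    result = {"unit_ids": uids, "R": R, "preferred_freq_hz": F, "rayleigh_p": P}
    coupled = np.flatnonzero((R > 0).any(axis=1))
    if coupled.size >= 20:
        seed = _stage_seed(cfg, "couple")
        cc = units.cluster_by_ic_coupling(
            R[coupled], k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
            seed=seed)
        assignment = np.full(len(uids), -1)
        assignment[coupled] = cc.assignment
        result.update({"coupling_cluster": assignment, "k": cc.k,
                       "silhouette": cc.silhouette})
    io.save_json(result, out / "coupling.json")
    return result


def stage_detect_connections(cfg: SessionConfig):
    cfg, root, out = _paths(cfg)
    spikes = _load_spikes(cfg, root)
    state_iv = io.load_intervals(out / "states.csv") if (out / "states.csv").exists() else []
    edges = conn.detect_network_edges(spikes, min_spikes=cfg.conn_min_spikes)
    per_edge = []
    for e in edges:
        if state_iv:
            st = conn.state_dependent_transmission(
                spikes.spike_times[e.pre], spikes.spike_times[e.post],
                state_iv, min_pre_spikes=cfg.conn_min_pre_spikes)
            for lab, v in st.items():
                if v is not None:
                    e.transmission[lab] = v["transmission"]
                    e.peak_to_baseline[lab] = v["peak_to_baseline"]
            per_edge.append(st)
    identity = conn.ccg_identity(edges)
    comparison = None
    if per_edge:
        try:
            n, med, p = conn.compare_state_transmission(per_edge)
            comparison = {"n_pairs": n, "median_wake_minus_nrem": med,
                          "signed_rank_p": p}
        except ValueError:
            comparison = None
    df = pd.DataFrame(
        [{"pre": e.pre, "post": e.post, "sign": e.sign,
          "ambiguous": e.ambiguous,
          "lags_ms": ";".join(f"{l:.2f}" for l in e.significant_lags_ms),
          **{f"p_{k.lower()}": v for k, v in e.transmission.items()},
          } for e in edges])
    df.to_csv(out / "edges.csv", index=False)
    io.save_json({"ccg_identity": {str(k): v for k, v in identity.items()},
                  "state_comparison": comparison}, out / "connectivity.json")
    return edges, identity, comparison


# --------------------------------------------------------------------------
# orchestration


def run_all(cfg: SessionConfig) -> dict:
    """Run every stage in order and assemble the session report.

    Deterministic given the config (including seed); a stage failure
    aborts with the stage name while preserving completed outputs.
    """
    cfg = cfg.resolve()
    stage_fns = [
        ("score_states", stage_score_states),
        ("detect_slowwaves", stage_detect_slowwaves),
        ("laminar_map", stage_laminar_map),
        ("classify_units", stage_classify_units),
        ("couple", stage_couple),
        ("detect_connections", stage_detect_connections),
    ]
    for name, fn in stage_fns:
        try:
            fn(cfg)
        except Exception as err:  # noqa: BLE001 - annotate stage and re-raise
            raise StageError(name, err) from err
    return collate_report(cfg)


def collate_report(cfg: SessionConfig) -> dict:
    """Merge per-stage outputs into one JSON report (also human-readable
    summary text)."""
    cfg, root, out = _paths(cfg)
    report: dict = {"config_hash": cfg.hash(), "seed": cfg.seed}

    states_f = out / "states.csv"
    if states_f.exists():
        iv = io.load_intervals(states_f)
        report["states"] = {
            lab: round(sum(e - s for s, e, l in iv if l == lab), 3)
            for lab in sorted({l for _, _, l in iv})}
    du_f = out / "downup.csv"
    if du_f.exists():
        du = io.load_intervals(du_f)
        report["n_down_states"] = sum(1 for *_, lab in du if lab == "DOWN")
    lm_f = out / "laminar_map.json"
    if lm_f.exists():
        lm = io.load_json(lm_f)
        report["landmarks_um"] = lm.get("landmarks_um", {})
        report["n_coherence_clusters"] = lm.get("n_clusters")
        report["cluster_consistency"] = lm.get("cluster_consistency")
        report["ic_relative_power"] = lm.get("ic_relative_power")
    units_f = out / "units.csv"
    if units_f.exists():
        u = pd.read_csv(units_f)
        if "waveform_class" in u:
            report["unit_class_counts"] = u["waveform_class"].value_counts().to_dict()
        if "down_active" in u:
            report["n_down_active"] = int(u["down_active"].fillna(False).sum())
    cp_f = out / "coupling.json"
    if cp_f.exists():
        cp = io.load_json(cp_f)
        if "k" in cp:
            report["n_coupling_clusters"] = cp["k"]
    cn_f = out / "connectivity.json"
    if cn_f.exists():
        cn = io.load_json(cn_f)
        report["state_comparison"] = cn.get("state_comparison")
    edges_f = out / "edges.csv"
    if edges_f.exists():
        ed = pd.read_csv(edges_f)
        report["edge_counts"] = ({} if ed.empty
                                 else ed["sign"].value_counts().to_dict())

    io.save_json(report, out / "report.json")
    lines = [f"session report (config {report['config_hash']})"]
    for k, v in report.items():
        if k != "config_hash":
            lines.append(f"  {k}: {v}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report


# --------------------------------------------------------------------------
# synthetic session writer (used by the CLI `simulate` subcommand)


def write_synthetic_session(cfg_sim, directory) -> Path:
    """Simulate a session and write it in the on-disk layout the pipeline
    consumes (plus the ground truth sidecar)."""
    from . import synthetic

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rec, spikes, events, truth = synthetic.simulate_session(cfg_sim)
    io.write_recording(rec, directory / "lfp.lfp")
    wb = synthetic.simulate_wideband_snippet(cfg_sim)
    io.write_recording(wb, directory / "wideband.dat")
    io.save_spikes(spikes, directory / "spikes")
    io.save_events(events, directory / "events.csv")
    io.save_json(truth.to_dict(), directory / "ground_truth.json")
    return directory
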