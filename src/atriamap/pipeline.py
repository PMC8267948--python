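"""End-to-end orchestration: simulate -> map -> conduction metrics -> ERP/APD,
per-preparation reports and descriptive group summaries (mean +- SEM).

Inferential statistics are deliberately out of scope; the pipeline ends at
descriptive per-group summaries."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .activation_mapping import DEFAULT_CONFIG, MappingConfig, build_activation_map
from .cellular_metrics import measure_apd
from .conduction_metrics import PERCENTILE_CONVENTION, conduction_result
from .errors import InsufficientDataError, InvalidParameterError
from .pacing_analysis import (
    BelowResolution,
    ProtocolConfig,
    default_protocol,
    erp_from_run,
    sweep_outcomes,
)
from .recording_io import ElectrodeGrid
from .synthetic_tissue import (
    PRESET_AP_NOISE_SD_MV,
    PRESET_NOISE_SD_MV,
    build_velocity_field,
    corner_position,
    preset_tissue,
    simulate_activation,
    synthesize_action_potential,
    synthesize_erp_sweep,
    synthesize_s1_train,
)

log = logging.getLogger("atriamap")

SCHEMA_VERSION = "1"

#: number of steady-state drive-train beats pooled per cycle length for mapping
N_MAPPING_BEATS = 5

CONVENTIONS = {
    "percentile": PERCENTILE_CONVENTION,
    "apd_reference": "maximum-upstroke time",
    "lat_rule": "maximum |deviation| from baseline, threshold 5 robust SDs",
    "beat_pooling": f"last {N_MAPPING_BEATS} S1 beats of the mapping train per cycle length",
    "phase_pooling": "quadruplet values pooled across beats before percentiles",
}


@dataclass
class PreparationReport:
    """All measurements for one (synthetic) preparation."""

    prep_id: str
    preset: str
    seed: int
    config_hash: str
    conventions: dict
    conduction: list[dict]  # per cycle length
    erp: list[dict]  # per corner x cycle length
    apd: dict
    ground_truth: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


@dataclass
class GroupSummary:
    group: str
    metric: str
    cycle_length_ms: float | None
    n: int
    mean: float
    sem: float | None


def _config_hash(obj: dict) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:12]


def run_preparation(
    preset: str,
    seed: int,
    *,
    protocol: ProtocolConfig | None = None,
    grid: ElectrodeGrid | None = None,
    noise_sd_mv: float = PRESET_NOISE_SD_MV,
    ap_noise_sd_mv: float = PRESET_AP_NOISE_SD_MV,
    mapping_config: MappingConfig = DEFAULT_CONFIG,
    prep_id: str | None = None,
) -> PreparationReport:
    """Simulate and analyse one preparation; deterministic given (preset, seed)."""
    protocol = protocol or default_protocol()
    grid = grid or ElectrodeGrid()
    tissue = preset_tissue(preset, seed=seed)
    ss = np.random.SeedSequence(seed)
    seed_field, seed_map, seed_erp, seed_ap = (
        int(s.generate_state(1)[0] >> 1) for s in ss.spawn(4)
    )

    field = build_velocity_field(
        grid,
        tissue.velocity_mean_mps,
        tissue.velocity_cv_frac,
        tissue.correlation_length_mm,
        seed=seed_field,
    )
    act_by_corner = {
        corner: simulate_activation(field, corner_position(field, corner))
        for corner in protocol.corners
    }
    map_corner = protocol.corners[0]

    # conduction mapping: a dedicated constant-capture S1 train per cycle length
    conduction: list[dict] = []
    rng_map = np.random.default_rng(seed_map)
    for cl in protocol.cycle_lengths_ms:
        rec = synthesize_s1_train(
            act_by_corner[map_corner],
            grid,
            cl,
            n_beats=protocol.n_s1,
            corner=map_corner,
            noise_sd_mv=noise_sd_mv,
            seed=int(rng_map.integers(2**31)),
            tissue=tissue,
        )
        n_events = len(rec.stimulus_log)
        beats = range(max(0, n_events - N_MAPPING_BEATS), n_events)
        maps = [build_activation_map(rec, b, config=mapping_config) for b in beats]
        maps = [m for m in maps if m.n_annotated >= 3]
        if not maps:
            raise InsufficientDataError(f"no usable activation maps at CL {cl} ms")
        res = conduction_result(maps, cycle_length_ms=cl)
        conduction.append(
            {
                "cl_ms": cl,
                "cv_mps": res.cv_mean_mps,
                "chi": res.chi,
                "tat_ms": res.tat_ms,
                "n_triangles": len(res.cv_vectors),
                "n_phase_values": int(res.phase.values_ms.size),
                "n_maps": res.n_maps,
                "percentile_convention": PERCENTILE_CONVENTION,
            }
        )

    # ERP: triplicate decremental S2 sweeps per corner and cycle length
    erp_entries: list[dict] = []
    rng_erp = np.random.default_rng(seed_erp)
    for corner in protocol.corners:
        for cl in protocol.cycle_lengths_ms:
            replicates: list[float | BelowResolution] = []
            for rep in range(protocol.n_replicates):
                sweep = synthesize_erp_sweep(
                    act_by_corner[corner],
                    grid,
                    tissue,
                    cl,
                    protocol,
                    corner=corner,
                    replicate=rep,
                    noise_sd_mv=noise_sd_mv,
                    seed=int(rng_erp.integers(2**31)),
                )
                replicates.append(
                    erp_from_run(sweep_outcomes(sweep, config=mapping_config))
                )
            finite = [float(r) for r in replicates if not isinstance(r, BelowResolution)]
            erp_entries.append(
                {
                    "corner": corner,
                    "cl_ms": cl,
                    "replicates_ms": [
                        None if isinstance(r, BelowResolution) else float(r)
                        for r in replicates
                    ],
                    "mean_ms": float(np.mean(finite)) if finite else None,
                }
            )

    # intracellular APD from one synthetic action potential
    trace = synthesize_action_potential(
        tissue.apd_targets_ms, noise_sd_mv=ap_noise_sd_mv, seed=seed_ap
    )
    apd_res = measure_apd(trace)
    apd_entry = {
        "apd20_ms": apd_res.apd20_ms,
        "apd50_ms": apd_res.apd50_ms,
        "apd90_ms": apd_res.apd90_ms,
        "amplitude_mv": apd_res.amplitude_mv,
        "resting_mv": apd_res.resting_mv,
    }

    cfg = {
        "preset": preset,
        "protocol": asdict(protocol),
        "grid": {"rows": grid.rows, "cols": grid.cols, "spacing_mm": grid.spacing_mm},
        "noise_sd_mv": noise_sd_mv,
        "ap_noise_sd_mv": ap_noise_sd_mv,
        "mapping": asdict(mapping_config),
    }
    truth = {
        "velocity_mean_mps": tissue.velocity_mean_mps,
        "velocity_cv_frac": tissue.velocity_cv_frac,
        "erp_true_ms": {f"{cl:g}": tissue.erp_true_ms(cl) for cl in protocol.cycle_lengths_ms},
        "apd_targets_ms": list(tissue.apd_targets_ms),
    }
    return PreparationReport(
        prep_id=prep_id or f"{preset}-s{seed}",
        preset=preset,
        seed=seed,
        config_hash=_config_hash(cfg),
        conventions=dict(CONVENTIONS),
        conduction=conduction,
        erp=erp_entries,
        apd=apd_entry,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def _report_metrics(report: PreparationReport) -> list[tuple[str, float | None, float | None]]:
    """(metric, cycle_length, value) triples for one report."""
    rows: list[tuple[str, float | None, float | None]] = []
    for entry in report.conduction:
        cl = entry["cl_ms"]
        rows.append(("cv_mps", cl, entry["cv_mps"]))
        rows.append(("chi", cl, entry["chi"]))
        rows.append(("tat_ms", cl, entry["tat_ms"]))
    by_cl: dict[float, list[float]] = {}
    for entry in report.erp:
        rows.append((f"erp_ms_{entry['corner'].lower()}", entry["cl_ms"], entry["mean_ms"]))
        if entry["mean_ms"] is not None:
            by_cl.setdefault(entry["cl_ms"], []).append(entry["mean_ms"])
    for cl, vals in by_cl.items():
        rows.append(("erp_ms", cl, float(np.mean(vals))))
    for key in ("apd20_ms", "apd50_ms", "apd90_ms"):
        rows.append((key, None, report.apd[key]))
    return rows


def summarize_groups(
    reports: list[PreparationReport], grouping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Descriptive per-group summaries: mean and SEM (sd / sqrt(n)) per metric.

    ``grouping`` maps prep_id to a group label; by default each preset is a
    group.  Groups of size 1 get mean only, with SEM absent (and a warning)."""
    if not reports:
        raise InvalidParameterError("no reports to summarize")
    rows = []
    for rep in reports:
        group = (grouping or {}).get(rep.prep_id, rep.preset)
        for metric, cl, value in _report_metrics(rep):
            if value is not None:
                rows.append({"group": group, "metric": metric, "cl_ms": cl, "value": value})
    df = pd.DataFrame(rows)
    out = []
    for (group, metric, cl), sub in df.groupby(["group", "metric", "cl_ms"], dropna=False):
        n = len(sub)
        mean = float(sub["value"].mean())
        if n >= 2:
            sem = float(sub["value"].std(ddof=1) / np.sqrt(n))
        else:
            log.warning("group %s has a single preparation for %s; SEM omitted", group, metric)
            sem = None
        out.append(
            {
                "group": group,
                "metric": metric,
                "cl_ms": None if pd.isna(cl) else float(cl),
                "mean": mean,
                "sem": sem,
                "n": n,
            }
        )
    return pd.DataFrame(out, columns=["group", "metric", "cl_ms", "mean", "sem", "n"])


def run_group_experiment(
    presets: list[str],
    n_per_group: int,
    seed_base: int = 100,
    **kwargs,
) -> list[PreparationReport]:
    """Run ``n_per_group`` preparations per preset with consecutive seeds."""
    reports = []
    for gi, preset in enumerate(presets):
        for i in range(n_per_group):
            reports.append(
                run_preparation(preset, seed=seed_base + 1000 * gi + i, **kwargs)
            )
    return reports
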