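"""Ground-truth recovery experiments for every pipeline stage.

Each function simulates data under the study's acquisition conditions,
runs the corresponding analysis stage blind, scores it against the
simulator's truth record, and returns the summary metrics. These are the
computations behind the analysis scripts and the acceptance checks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import coloc, em, ephys, exo, kymo, simulate, statsflow

__all__ = [
    "transport_recovery",
    "truth_fed_flux_check",
    "event_recovery",
    "em_zone_recovery",
    "em_area_monte_carlo",
    "coloc_recovery",
    "ppr_recovery",
    "null_rejection_rate",
    "rout_calibration",
]


# ---------------------------------------------------------------------------
# transport


def _match_track(track: kymo.Track, positions_by_vesicle: np.ndarray) -> int | None:
    """Modal truth vesicle of a track (frames within 0.5 µm), or None."""
    d = np.abs(positions_by_vesicle[track.frames, :] - track.positions_um[:, None])
    nearest = np.argmin(d, axis=1)
    close = d[np.arange(len(nearest)), nearest] < 0.5
    if not close.any():
        return None
    return int(np.bincount(nearest[close]).argmax())


def transport_recovery(seed: int, snr: float = 8.0, n_vesicles: int = 30) -> dict:
    """Track one simulated axon blind and score against truth.

    Classification accuracy is per track against the class of the matched
    truth trajectory over the track's own frame window (the class of an
    unobserved part of a recording is not knowable from the track), with the
    same classifier applied to both. Speed error compares the blind
    per-axon mean segmental anterograde speed with the truth-fed one.
    """
    cfg = simulate.TransportSimConfig(
        n_vesicles=n_vesicles, seed=seed,
        amplitude=simulate.amplitude_for_snr(snr, 100.0),
    )
    movie, truth = simulate.simulate_axonal_movie(cfg)
    y = cfg.image_half_height
    path = kymo.AxonPath(
        [[0, y], [movie.shape[2] - 1, y]], width=5.0
    )
    tracks = kymo.detect_and_link(movie, path, cfg.pixel_size, cfg.frame_interval)
    P = truth.positions.pivot(index="frame", columns="vesicle", values="position_um").values

    correct = total = 0
    for tr in tracks:
        v = _match_track(tr, P)
        if v is None:
            continue
        frames = np.arange(tr.frames[0], tr.frames[-1] + 1)
        truth_tr = kymo.Track(-1, frames, P[frames, v], cfg.frame_interval)
        kymo.segment_track(truth_tr)
        kymo.segment_track(tr)
        if tr.too_short or truth_tr.too_short:
            continue
        total += 1
        correct += kymo.classify_vesicle(tr) == kymo.classify_vesicle(truth_tr)

    summary = kymo.summarize_axon(tracks, duration_s=cfg.duration)
    truth_summary = kymo.summarize_axon(
        kymo.tracks_from_truth(truth.positions, cfg.frame_interval), duration_s=cfg.duration
    )
    return {
        "accuracy": correct / total if total else float("nan"),
        "n_scored": total,
        "antero_speed": summary.mean_antero_speed,
        "antero_speed_truth": truth_summary.mean_antero_speed,
        "speed_rel_error": abs(summary.mean_antero_speed - truth_summary.mean_antero_speed)
        / truth_summary.mean_antero_speed,
        "net_flux": summary.net_flux_per_100um_min,
        "net_flux_truth": truth_summary.net_flux_per_100um_min,
    }


def truth_fed_flux_check(seed: int = 0) -> dict:
    """Feed truth trajectories through the summary; counts must be exact."""
    cfg = simulate.TransportSimConfig(seed=seed)
    _, truth = simulate.simulate_axonal_movie(cfg)
    tracks = kymo.tracks_from_truth(truth.positions, cfg.frame_interval)
    summ = kymo.summarize_axon(tracks, duration_s=cfg.duration)
    classes = truth.vesicles["class"].value_counts()
    flux_truth = float(classes.get("anterograde", 0) - classes.get("retrograde", 0))
    return {
        "net_flux": summ.net_flux_per_100um_min,
        "net_flux_truth": flux_truth,
        "counts": (summ.n_anterograde, summ.n_retrograde, summ.n_static),
        "counts_truth": tuple(
            int(classes.get(k, 0)) for k in ("anterograde", "retrograde", "static")
        ),
    }


# ---------------------------------------------------------------------------
# exocytosis


def event_recovery(seed: int, snr: float = 5.0, amplitude: float = 50.0) -> dict:
    """Detect events blind on one simulated field; recall/precision vs truth.

    SNR is defined on the ROI-mean trace: ``amplitude / sigma_trace``; a
    detection matches a truth event on the same ROI within 2 frames.
    """
    roi_radius = 4
    n_pix = np.sum(
        (np.arange(-roi_radius, roi_radius + 1)[:, None] ** 2
         + np.arange(-roi_radius, roi_radius + 1) ** 2) <= roi_radius**2
    )
    noise_sd = amplitude / snr * np.sqrt(n_pix)
    fields, rois, truth = simulate.simulate_phluorin_movie(
        n_fields=1, event_amplitude=amplitude, noise_sd=noise_sd, seed=seed
    )
    roi_objs = [
        exo.SynapseROI(int(r.roi), (r.y, r.x), r.radius, int(r.field))
        for r in rois.itertuples()
    ]
    tp = fp = fn = 0
    for epoch, movies in (("pre", [fields[0]["pre"]]), ("post", fields[0]["post"])):
        for a, movie in enumerate(movies):
            detected = {
                (e.roi_id, e.onset_frame)
                for e in exo.detect_events(movie, roi_objs, dF_threshold=amplitude / 2, epoch=epoch)
            }
            te = truth.events.query("field == 0 and epoch == @epoch and acquisition == @a")
            matched: set = set()
            for t in te.itertuples():
                hits = sorted(
                    (abs(d[1] - t.onset_frame), d)
                    for d in detected
                    if d[0] == t.roi and abs(d[1] - t.onset_frame) <= 2 and d not in matched
                )
                if hits:
                    matched.add(hits[0][1])
                    tp += 1
                else:
                    fn += 1
            fp += len(detected) - len(matched)
    return {
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "n_events": tp + fn,
    }


# ---------------------------------------------------------------------------
# EM


def em_zone_recovery(n_geometries: int = 100, seed: int = 0) -> dict:
    """Per-zone counts on simulated synapses must equal truth exactly."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_geometries):
        mix = rng.dirichlet((3, 3, 3, 3))
        geom, truth = simulate.simulate_em_synapse(
            terminal_shape=simulate.default_terminal_shape(
                rng.uniform(700, 1000), rng.uniform(400, 600)
            ),
            n_vesicles=int(rng.integers(10, 30)),
            zone_mix=tuple(mix),
            seed=int(rng.integers(1 << 31)),
        )
        part = em.partition_zones(geom)
        asn = em.assign_vesicles(geom, part)
        truth_counts = np.array([(truth.zones["zone"] == k).sum() for k in range(3)])
        exact += int(
            np.array_equal(truth_counts, asn["zone_counts"])
            and (truth.zones["zone"] == -1).sum() == asn["n_beyond"]
        )
    return {"exact_fraction": exact / n_geometries, "n_geometries": n_geometries}


def em_area_monte_carlo(seed: int = 0, n_samples: int = 1_000_000) -> dict:
    """Polygon-clipped zone areas vs rejection sampling."""
    geom, _ = simulate.simulate_em_synapse(seed=seed)
    part = em.partition_zones(geom)
    mc = em.monte_carlo_zone_areas(
        geom, n_samples=n_samples, rng=np.random.default_rng(seed + 1)
    )
    rel = np.abs(mc / part.areas_um2 - 1)
    return {"max_rel_error": float(rel.max()), "rel_errors": rel.tolist()}


# ---------------------------------------------------------------------------
# colocalization


def coloc_recovery(seed: int, coloc_fraction: float = 0.5, n_puncta: int = 60) -> dict:
    """Blind percent colocalization on a simulated two-channel field."""
    img_a, img_b, truth = simulate.simulate_two_channel_puncta(
        n_puncta=n_puncta, coloc_fraction=coloc_fraction, seed=seed
    )
    diam = 4.0
    res = coloc.make_masks_and_count(
        coloc.dog_enhance(img_a, diam), coloc.dog_enhance(img_b, diam), 5.0, 5.0
    )
    return {
        "percent": res["percent_colocalization"],
        "count_a": res["count_a"],
        "truth_percent": 100.0 * truth.puncta.query("channel == 'A'")["colocalized"].mean(),
    }


# ---------------------------------------------------------------------------
# electrophysiology


def ppr_recovery(
    isi: float, ppr_true: float, noise_sd: float, n_sweeps: int = 20, seed: int = 0
) -> dict:
    sweeps, _ = simulate.simulate_epsc_pair(
        isi=isi, ppr_true=ppr_true, noise_sd=noise_sd, n_sweeps=n_sweeps, seed=seed
    )
    res = ephys.compute_ppr(sweeps)
    return {
        "mean_ppr": res.mean_ppr,
        "ppr_of_means": res.ppr_of_means,
        "abs_error": abs(res.mean_ppr - ppr_true),
        "rel_error": abs(res.mean_ppr - ppr_true) / ppr_true,
    }


# ---------------------------------------------------------------------------
# statistics workflow


def null_rejection_rate(
    n_sims: int = 2000, n_per_group: int = 15, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Type-I error of the full workflow on identical Gaussian groups."""
    rng = np.random.default_rng(seed)
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_sims):
            df = pd.DataFrame(
                {
                    "value": rng.normal(0.0, 1.0, 2 * n_per_group),
                    "group": ["a"] * n_per_group + ["b"] * n_per_group,
                }
            )
            report = statsflow.run_workflow(statsflow.GroupTable(df), alpha=alpha)
            rejections += report.pvalue < alpha
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims}


def rout_calibration(n_sims: int = 1000, n: int = 50, seed: int = 0) -> dict:
    """False-flag rate on clean Gaussians and hit rate on a 10-sigma point."""
    rng = np.random.default_rng(seed)
    false_fractions = []
    for _ in range(n_sims):
        _, _, flagged = statsflow.rout_outliers(rng.normal(0.0, 1.0, n))
        false_fractions.append(flagged.mean())
    hits = 0
    n_hit_trials = 200
    for _ in range(n_hit_trials):
        values = np.append(rng.normal(0.0, 1.0, 100), 10.0)
        _, _, flagged = statsflow.rout_outliers(values)
        hits += bool(flagged[-1])
    return {
        "false_flag_fraction": float(np.mean(false_fractions)),
        "contaminant_hit_rate": hits / n_hit_trials,
    }
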