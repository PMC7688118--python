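"""End-to-end analysis: detections in, contingent tables out.

Stages, in order: daily mean positions per fish-year; gap imputation; run
extraction at the entry/exit threshold; catenation/padding to the cohort
axis; DTW + k-medoids clustering of the first year; nearest-centroid
classification of the second year onto the first year's centroids (aligned
by day of year); cross-year contingency; run-timing statistics with
experienced temperature; and last-detection survival analysis (loss rates,
Kaplan-Meier, Peto-Peto test).

Cluster indices are mapped to contingent names by the up-estuary extent of
their centroid: the cluster whose medoid peaks furthest upriver is "upper",
the other "lower" (with k != 2, names are "contingent_1..k" ordered by
peak). Every fish-year seen in the detections is dispositioned as exactly
one of assigned / skipped-spawning / excluded, with a logged reason.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import phenology as ph
from . import preprocess as pp
from . import survival as sv
from .config import PipelineConfig
from .errors import EmptyCohortError
from .io import local_date, write_table


@dataclass
class AnalysisReport:
    series: pd.DataFrame
    assignments: pd.DataFrame
    crossclass: pd.DataFrame
    phenology: pd.DataFrame
    survival: pd.DataFrame
    km_curves: pd.DataFrame
    tests: pd.DataFrame
    loss_rates: pd.DataFrame
    disposition: pd.DataFrame
    log_lines: list[str] = field(default_factory=list)

    _TABLES = (
        "series",
        "assignments",
        "crossclass",
        "phenology",
        "survival",
        "km_curves",
        "tests",
        "loss_rates",
        "disposition",
    )

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            write_table(getattr(self, name), out / f"{name}.csv", name)
        (out / "run.log").write_text("\n".join(self.log_lines) + "\n")


def _doy(date: dt.date) -> int:
    return (date - dt.date(date.year, 1, 1)).days


def _pad_to_doy_axis(start_doy, values, axis_start, axis_len, pad_km):
    out = np.full(axis_len, float(pad_km))
    off = start_doy - axis_start
    out[off : off + len(values)] = values
    return out


def _contingent_names(centroids: list[np.ndarray], k: int) -> list[str]:
    peaks = [float(np.max(c)) for c in centroids]
    order = np.argsort(peaks)  # ascending: lowest peak first
    names = [""] * k
    if k == 2:
        names[order[0]] = "lower"
        names[order[1]] = "upper"
    else:
        for rank, idx in enumerate(order):
            names[idx] = f"contingent_{rank + 1}"
    return names


def run_pipeline(
    config: PipelineConfig,
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    fish: pd.DataFrame,
    environment: pd.DataFrame,
) -> AnalysisReport:
    """Run the full contingent analysis; deterministic for fixed inputs."""
    log: list[str] = []
    dets = detections.copy()
    dets["date"] = local_date(dets["timestamp"], config.utc_offset_hours)
    dets["year"] = [d.year for d in dets["date"]]
    riverine_ids = set(receivers.loc[receivers["river_km"].notna(), "receiver_id"])

    # --- daily positions, imputation, run extraction, disposition
    segments: dict[int, list[pp.RunSegment]] = {}
    disposition_rows = []
    all_years = sorted(dets["year"].unique())
    for tag, tag_dets in dets.groupby("tag_id"):
        positions = pp.daily_mean_position(
            tag_dets, receivers, config.utc_offset_hours
        )
        for year in all_years:
            if not (tag_dets["year"] == year).any():
                continue
            year_pos = positions[[d.year == year for d in positions.index]]
            if len(year_pos) == 0:
                disposition_rows.append(
                    (tag, year, "skipped", "no in-river detections this year")
                )
                continue
            if len(year_pos) < 2:
                disposition_rows.append(
                    (tag, year, "excluded", "fewer than 2 in-river observed days")
                )
                continue
            dense = pp.impute_gaps(year_pos, config.imputation_window_days)
            seg = pp.extract_run(dense, tag, year, config.entry_exit_threshold_km)
            if seg is None:
                disposition_rows.append(
                    (tag, year, "skipped", "never crossed entry threshold")
                )
                continue
            segments.setdefault(year, []).append(seg)
            disposition_rows.append((tag, year, "assigned", "run detected"))
    run_years = sorted(segments)
    if not run_years:
        raise EmptyCohortError("no fish passed the run-detection criteria")
    year1 = run_years[0]
    year2 = run_years[1] if len(run_years) > 1 else None

    # --- year-1 clustering
    padded1 = pp.catenate_pad(segments[year1], config.pad_km)
    values1 = [s.values for s in padded1]
    D = cl.dissimilarity_matrix(values1, config.dtw_step_pattern)
    model = cl.pam_cluster(D, k=config.n_clusters)
    cl.extract_centroids(model, values1)
    names = _contingent_names(model.centroids, config.n_clusters)
    labels1 = {
        s.tag_id: names[int(a)] for s, a in zip(padded1, model.assignments)
    }
    log.append(
        f"year {year1}: clustered {len(padded1)} fish into {config.n_clusters} "
        f"contingents; medoid tags "
        f"{[padded1[m].tag_id for m in model.medoid_indices]}; "
        f"total within-cluster DTW cost {model.total_cost:.1f}"
    )
    assign_rows = [
        {
            "tag_id": s.tag_id,
            "year": year1,
            "cluster": names[int(a)],
            "distance_to_centroid": float(
                model.dissimilarity[i, model.medoid_indices[int(a)]]
            ),
            "tie_flag": False,
        }
        for i, (s, a) in enumerate(zip(padded1, model.assignments))
    ]

    # --- year-2 classification onto year-1 centroids (day-of-year axis)
    labels2: dict[str, str] = {}
    padded2: list[pp.PhenologySeries] = []
    if year2 is not None:
        padded2 = pp.catenate_pad(segments[year2], config.pad_km)
        cen_start = _doy(padded1[0].dates[0])
        new_start = _doy(padded2[0].dates[0])
        axis_start = min(cen_start, new_start)
        axis_end = max(
            cen_start + len(padded1[0].dates), new_start + len(padded2[0].dates)
        )
        axis_len = axis_end - axis_start
        cen = [
            _pad_to_doy_axis(cen_start, c, axis_start, axis_len, config.pad_km)
            for c in model.centroids
        ]
        new = [
            _pad_to_doy_axis(new_start, s.values, axis_start, axis_len, config.pad_km)
            for s in padded2
        ]
        y2_labels, y2_dist, y2_ties = cl.classify_to_centroids(
            new, cen, config.dtw_step_pattern
        )
        for s, lab, d, tie in zip(padded2, y2_labels, y2_dist, y2_ties):
            labels2[s.tag_id] = names[int(lab)]
            assign_rows.append(
                {
                    "tag_id": s.tag_id,
                    "year": year2,
                    "cluster": names[int(lab)],
                    "distance_to_centroid": float(d),
                    "tie_flag": bool(tie),
                }
            )
        log.append(
            f"year {year2}: classified {len(padded2)} fish onto year-{year1} centroids"
        )

    assignments = pd.DataFrame(assign_rows)

    # --- cross-classification
    if year2 is not None and set(labels1) & set(labels2):
        xc = cl.cross_classify(labels1, labels2)
        cells = [
            {
                "year1_label": i,
                "year2_label": j,
                "count": int(xc.table.loc[i, j]),
                "concordance": xc.concordance,
                "chi2": xc.chi2,
                "df": xc.df,
                "p_value": xc.p_value,
                "n_shared": xc.n_shared,
            }
            for i in xc.table.index
            for j in xc.table.columns
        ]
        crossclass = pd.DataFrame(cells)
        log.append(
            f"cross-classification: {xc.n_shared} shared fish, "
            f"concordance {100 * xc.concordance:.0f}%, chi2 {xc.chi2:.2f} "
            f"(df {xc.df}, p {xc.p_value:.3g})"
        )
    else:
        crossclass = pd.DataFrame(
            columns=[
                "year1_label", "year2_label", "count", "concordance",
                "chi2", "df", "p_value", "n_shared",
            ]
        )

    # --- phenology
    label_of_year = {year1: labels1}
    if year2 is not None:
        label_of_year[year2] = labels2
    phen_rows = []
    for year, labels in label_of_year.items():
        by_group: dict[str, list[pp.RunSegment]] = {}
        for seg in segments[year]:
            if seg.tag_id in labels:
                by_group.setdefault(labels[seg.tag_id], []).append(seg)
        for group in sorted(by_group):
            st = ph.run_stats(by_group[group], group, year, environment)
            phen_rows.append(
                {
                    "contingent": st.contingent,
                    "year": st.year,
                    "n_fish": st.n_fish,
                    "first_entry": st.first_entry,
                    "median_entry": st.median_entry,
                    "last_entry": st.last_entry,
                    "first_exit": st.first_exit,
                    "median_exit": st.median_exit,
                    "last_exit": st.last_exit,
                    "date_50pct_incidence": st.date_50pct_incidence,
                    "temp_at_50pct_C": st.temp_at_50pct,
                }
            )
    phenology = pd.DataFrame(phen_rows)

    # --- survival (groups fixed to the year-1 classification where known)
    analysis_end = config.analysis_end or max(dets["date"])
    last_detection = dets.groupby("tag_id")["date"].max().to_dict()
    group_of = dict(labels2)
    group_of.update(labels1)  # year-1 label wins where both exist
    entry_of_year = {
        y: {s.tag_id: s.entry_date for s in segments[y]} for y in run_years
    }
    surv_rows, km_frames, test_rows, z_rows = [], [], [], []
    for year in run_years:
        next_entries = entry_of_year.get(year + 1, {})
        origins, ends, events = {}, {}, {}
        for seg in segments[year]:
            tag = seg.tag_id
            if tag not in group_of:
                continue
            origins[tag] = seg.exit_date
            if tag in next_entries:
                ends[tag] = next_entries[tag]
                events[tag] = False
            else:
                last = min(last_detection[tag], analysis_end)
                if (analysis_end - last).days <= config.censor_window_days:
                    ends[tag] = analysis_end
                    events[tag] = False
                else:
                    ends[tag] = max(last, origins[tag])
                    events[tag] = True
        records = [
            sv.SurvivalRecord(tag, group_of[tag], origins[tag], ends[tag], events[tag])
            for tag in origins
        ]
        by_group: dict[str, list[sv.SurvivalRecord]] = {}
        for r in records:
            by_group.setdefault(r.group, []).append(r)
            surv_rows.append(
                {
                    "tag_id": r.tag_id,
                    "year": year,
                    "group": r.group,
                    "origin_date": r.origin_date,
                    "end_date": r.end_date,
                    "time_days": r.time_days,
                    "event": r.event,
                }
            )
        for group in sorted(by_group):
            curve = sv.kaplan_meier(by_group[group])
            km_frames.append(sv.km_table(curve, group, year))
            try:
                fit = sv.loss_rate(sv.extant_counts(by_group[group]))
                z_rows.append(
                    {
                        "year": year,
                        "group": group,
                        "Z_per_day": fit.Z,
                        "intercept": fit.intercept,
                        "r_squared": fit.r_squared,
                        "n_dates": fit.n_dates,
                    }
                )
            except Exception as exc:  # too few usable days
                log.append(f"loss rate {group} {year}: not fitted ({exc})")
        groups = sorted(by_group)
        if len(groups) == 2:
            a, b = by_group[groups[0]], by_group[groups[1]]
            if any(r.event for r in a + b):
                test = sv.weighted_logrank(a, b, weights="peto-peto")
                test_rows.append(
                    {
                        "year": year,
                        "group_a": groups[0],
                        "group_b": groups[1],
                        "weights": test.weights,
                        "statistic": test.statistic,
                        "df": test.df,
                        "p_value": test.p_value,
                    }
                )
                log.append(
                    f"year {year} Peto-Peto: chi2 {test.statistic:.2f}, "
                    f"p {test.p_value:.3g}"
                )

    series = pp.series_table(padded1 + padded2)
    disposition = pd.DataFrame(
        disposition_rows, columns=["tag_id", "year", "status", "reason"]
    )
    return AnalysisReport(
        series=series,
        assignments=assignments,
        crossclass=crossclass,
        phenology=phenology,
        survival=pd.DataFrame(surv_rows),
        km_curves=(
            pd.concat(km_frames, ignore_index=True) if km_frames else pd.DataFrame()
        ),
        tests=pd.DataFrame(
            test_rows,
            columns=["year", "group_a", "group_b", "weights", "statistic", "df", "p_value"],
        ),
        loss_rates=pd.DataFrame(
            z_rows,
            columns=["year", "group", "Z_per_day", "intercept", "r_squared", "n_dates"],
        ),
        disposition=disposition,
        log_lines=log,
    )
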