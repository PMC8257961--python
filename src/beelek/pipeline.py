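"""End-to-end pipeline: tracks in, analysis tables out.

Glues the stages together in the order the analysis runs: substantial-flight
filtering, straight/convoluted classification, congregation-area discovery,
visit counting, swarm-dynamics summaries, and the occupancy heat map (which
consumes every segment, substantial or not).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import flightseg, lekfind, occupancy, swarmdyn, trackio


@dataclass
class PipelineResult:
    substantial: list[trackio.FlightSegment]
    rejected: list[trackio.FlightSegment]
    classified: list[tuple[trackio.FlightSegment, list[flightseg.FlightSection]]]
    sections: pd.DataFrame
    section_aggregates: dict
    congregations: list[lekfind.Congregation]
    visits: pd.DataFrame
    visits_per_flight: pd.DataFrame
    location_sections: pd.DataFrame
    location_stats: pd.DataFrame
    samples: pd.DataFrame
    well_fits: pd.DataFrame
    heatmap: occupancy.HeatGrid | None = None


def run_pipeline(
    segments: list[trackio.FlightSegment],
    site: trackio.SiteConfig,
    classifier_params: flightseg.ClassifierParams | None = None,
    cluster_params: lekfind.ClusterParams | None = None,
    bridge_params: occupancy.BridgeParams | None = None,
    build_heatmap: bool = True,
) -> PipelineResult:
    cp = classifier_params or flightseg.sections_from_params_dict(site.params.get("classifier"))
    kp = cluster_params or lekfind.cluster_params_from_dict(site.params.get("cluster"))

    kept, rejected = trackio.filter_substantial(segments)
    classified = flightseg.classify_dataset(kept, cp)
    sections_df, aggregates = flightseg.sections_table(classified)
    areas = lekfind.discover_congregations(classified, site.hives, kp)
    visits_df, per_flight = swarmdyn.visits_table(classified, areas)
    loc_sections, loc_stats, samples = swarmdyn.location_summary(classified, areas, site.hives)
    fits = swarmdyn.well_fits_table(samples)

    heat = None
    if build_heatmap and segments:
        bp = bridge_params or occupancy.BridgeParams()
        heat = occupancy.dataset_heatmap(segments, params=bp)

    return PipelineResult(
        substantial=kept,
        rejected=rejected,
        classified=classified,
        sections=sections_df,
        section_aggregates=aggregates,
        congregations=areas,
        visits=visits_df,
        visits_per_flight=per_flight,
        location_sections=loc_sections,
        location_stats=loc_stats,
        samples=samples,
        well_fits=fits,
        heatmap=heat,
    )
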