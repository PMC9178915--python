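"""End-to-end convenience runner: campaign -> three maps -> validation.

Chains the full analysis in memory: simulate (or accept) a campaign,
filter gross outliers, snap records to segments, temporally correct
against the reference station, aggregate to drive-pass means and the
data-only map, fit the LUR surface, fit the mixed model, and predict the
mixed map. Used by the command-line interface, the test-bench and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from segmap import ingest, lur, mixed, temporal
from segmap.synthetic import CampaignConfig, StreetNetwork, TruthSurface, simulate_campaign


@dataclass
class PipelineResult:
    network: StreetNetwork
    truth: TruthSurface | None
    records: pd.DataFrame
    pass_means: pd.DataFrame
    data_only: pd.DataFrame          # segment_id, mean_of_means, n_passes, sem
    lur_fit: lur.LURFit
    mixed_fit: mixed.MixedFit
    mixed_map: pd.DataFrame          # from predict_map
    filter_report: ingest.FilterReport

    @property
    def maps(self) -> dict[str, pd.Series]:
        """The three per-segment map products keyed by name."""
        mm = self.mixed_map.set_index("segment_id")
        return {
            "data_only": self.data_only.set_index("segment_id")["mean_of_means"],
            "lur": mm["lur_pred"],
            "mixed": mm["mixed_pred"],
        }


def run_pipeline(
    records: pd.DataFrame,
    network: StreetNetwork,
    reference: pd.DataFrame,
    *,
    truth: TruthSurface | None = None,
    max_dist: float = 50.0,
    window_spec: temporal.WindowSpec | None = None,
    correction_mode: str = "additive",
    gain_min: float = 0.01,
    p_remove: float = 0.10,
    freeze_beta: bool = False,
    method: str = "reml",
    facade_adjust: float | None = None,
) -> PipelineResult:
    """Run filter -> snap -> correct -> aggregate -> LUR -> mixed."""
    kept, report = ingest.filter_range(records)
    table = temporal.build_window_table(reference, window_spec or temporal.WindowSpec())
    corrected = temporal.correct(kept, table, mode=correction_mode)
    snapped = ingest.snap_records(corrected, network, max_dist)
    pass_means = ingest.aggregate_passes(snapped)
    data_only = ingest.summarize_segments(pass_means)
    lfit = lur.fit_lur(
        data_only, network.covariates, network.expected_signs,
        gain_min=gain_min, p_remove=p_remove,
    )
    mfit = mixed.fit_mixed_from_lur(
        pass_means, network.covariates, lfit,
        method=method, freeze_beta=freeze_beta,
    )
    mixed_map = mixed.predict_map(mfit, network, facade_adjust=facade_adjust)
    return PipelineResult(
        network=network,
        truth=truth,
        records=records,
        pass_means=pass_means,
        data_only=data_only,
        lur_fit=lfit,
        mixed_fit=mfit,
        mixed_map=mixed_map,
        filter_report=report,
    )


def run_synthetic_pipeline(config: CampaignConfig, **kwargs) -> PipelineResult:
    """Simulate a campaign from ``config`` and run the full pipeline on it."""
    network, truth, reference, records = simulate_campaign(config)
    return run_pipeline(records, network, reference, truth=truth, **kwargs)
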