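"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from capgrad import synthetic_data as sd
from capgrad.dwell_analysis import dwell_records, link_events, merge_colocated_tracks
from capgrad.end_tracking import mask_localizations
from capgrad.pipeline_io import child_seed


def run_cap_pipeline(cfg_factory, target_events, seed, **cfg_overrides):
    """simulate -> mask -> link -> merge -> dwell records, pooled over as many
    microtubules as the target event count requires."""
    base = cfg_factory(seed=0, **cfg_overrides)
    n_mt = sd.microtubules_for_events(base, target_events)
    records = []
    tracks = []
    offset = 0
    for i in range(n_mt):
        cfg = cfg_factory(seed=child_seed(seed, i), **cfg_overrides)
        locs, truth, trace = sd.simulate_cap_events(cfg)
        masked = mask_localizations(locs, trace)
        if len(masked.kept) == 0:
            continue
        linked = merge_colocated_tracks(link_events(masked.kept.reset_index(drop=True)))
        records.append(dwell_records(linked, trace, cfg.frame_interval))
        linked = linked.copy()
        linked["track_id"] += offset
        offset = linked["track_id"].max() + 1
        tracks.append(linked)
    return (
        pd.concat(records, ignore_index=True),
        pd.concat(tracks, ignore_index=True),
    )


@pytest.fixture(scope="session")
def wt_records():
    """Wildtype-like dwell records at a moderate event count (fast)."""
    records, _ = run_cap_pipeline(sd.wildtype_config, 1500, seed=11)
    return records


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
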