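"""End-to-end: simulate a small study, featurize, cross-validate the forest.

Ten synthetic patients whose hypotensive episodes are preceded by a 12 mmHg
MAP dip timed to fall inside the observation window — the forecastable
signature the classifier should find.
"""

import collections

from ibpforecast import cross_validate, learnable_study_config, simulate
from ibpforecast.pipeline import featurize_recordings
from ibpforecast.sampler import SamplerConfig

configs = learnable_study_config(10, seed=1, precursor_drop=12.0)
recordings = [simulate(c) for c in configs]
table, manifest = featurize_recordings(recordings, SamplerConfig())
print("labels:", dict(collections.Counter(table.labels)))

report = cross_validate(table, k=5, n_trees=100, seed=7, group_by_patient=True)
print(
    f"pooled: accuracy={report.pooled.accuracy:.3f} "
    f"precision={report.pooled.precision:.3f} recall={report.pooled.recall:.3f} "
    f"mean AUC={report.mean_auc:.3f}"
)
print("top features:", [(n, round(v, 3)) for n, v in report.top_features(5)])

# Recall and precision near 1 mean the forest recovers the injected precursor
# from the observation-window features alone, five minutes ahead of the
# event; the top features are the pressure-level statistics the dip shifts.
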