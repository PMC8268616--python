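"""Shared configuration for the numbered analysis drivers.

The reference synthetic study mirrors the structure of an annotated
scRNA-seq atlas plus six bulk survival cohorts: 6 cell subclusters of 500
cells each, 1000 genes with 20 planted markers per subcluster (detection
0.8 in-subcluster vs 0.02 elsewhere), six 250-sample bulk cohorts mixed
from the subcluster profiles with log-scale noise 0.1, and overall survival
in which subcluster SC1 carries a true hazard ratio of 1.5 per SD of its
mixture fraction.
"""
from pathlib import Path

SEED = 101
RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"

STUDY = dict(
    n_subclusters=6,
    cells_per_subcluster=500,
    n_genes=1000,
    markers_per_subcluster=20,
    n_cohorts=6,
    samples_per_cohort=250,
    noise_sd=0.1,
    beta_per_subcluster={"SC1": 0.4054651081081644},  # ln(1.5)
    censor_rate=0.3,
    seed=SEED,
)


def make_study():
    from phenosig.synthetic_data import simulate_study
    return simulate_study(**STUDY)
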