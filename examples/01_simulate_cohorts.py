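"""Generate the two synthetic cohorts and write them to disk.

Builds (a) an up-chirp cohort — every component's frequency rises over the
sequence, so its time direction is identifiable — and (b) a two-class
episodic cohort where patients carry short oscillatory bursts on top of
AR(1) noise. Prints the shapes and a zero-crossing check that the chirps
really do speed up.
"""

import numpy as np

from arrowtime import (
    ChirpParams,
    EpisodicCohortParams,
    generate_chirp_cohort,
    generate_episodic_cohort,
    write_cohort,
)

chirp = generate_chirp_cohort(
    8, ChirpParams(n_components=6, n_timepoints=160, seed=0)
)
episodic = generate_episodic_cohort(
    EpisodicCohortParams(n_patients=6, n_controls=6, n_components=6,
                         n_timepoints=160, event_amplitude=4.0, seed=0)
)

manifest = write_cohort(chirp, "scratch/example_data/pretrain")
print(f"chirp cohort: {len(chirp)} subjects of shape "
      f"({chirp.n_timepoints}, {chirp.n_components}) -> {manifest}")

x = chirp.subjects[0].values[:, 0]
half = len(x) // 2
zc = lambda v: int(np.sum(np.diff(np.sign(v)) != 0))
print(f"zero crossings, first half vs second half: {zc(x[:half])} vs {zc(x[half:])} "
      "(more crossings later = rising frequency = readable arrow of time)")

manifest2 = write_cohort(episodic, "scratch/example_data/downstream")
print(f"episodic cohort: {len(episodic)} subjects, "
      f"{int(episodic.labels.sum())} patients -> {manifest2}")
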