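"""Two state lines sharing an origin form 2-D differentiation coordinates.

Two differentiation directions starting from the same pluripotent state
(think: neuronal and blast-cell differentiation of ES cells) give each
sample a pair of centered projections — a "differentiation index
coordinate" locating it relative to both programs at once.
"""

import numpy as np

from devstate import (
    ExpressionTable,
    TimeCourse,
    differentiation_coordinates,
    fit_state_line,
)
from devstate.simulate import straight_trajectory_along

rng = np.random.default_rng(21)
n = 30
shared_origin = rng.normal(8.0, 1.0, size=n)

# two orthogonal differentiation directions leaving the same start state
d_neuro = rng.normal(size=n)
d_neuro /= np.linalg.norm(d_neuro)
d_blast = rng.normal(size=n)
d_blast -= (d_blast @ d_neuro) * d_neuro
d_blast /= np.linalg.norm(d_blast)

labels = ["ES", "day3", "day6"]
tc_neuro = straight_trajectory_along(d_neuro, labels, [1.0, 1.5], base=shared_origin)
tc_blast = straight_trajectory_along(d_blast, labels, [1.2, 1.3], base=shared_origin)
line_neuro = fit_state_line(tc_neuro, metadata={"name": "neuronal"})
line_blast = fit_state_line(tc_blast, metadata={"name": "blast"})

samples = ExpressionTable(
    gene_ids=tc_neuro.gene_ids,
    sample_ids=["ES_cell", "neuro_committed", "blast_committed", "mixed"],
    values=np.column_stack([
        shared_origin,
        shared_origin + 2.0 * d_neuro,
        shared_origin + 1.5 * d_blast,
        shared_origin + 1.0 * d_neuro + 1.0 * d_blast,
    ]),
)
coords = differentiation_coordinates(line_neuro, line_blast, samples)
print(coords.to_frame().round(4))

print()
print("The ES sample sits at the shared origin (0, 0); committed samples")
print("advance along exactly one axis; the mixed sample advances on both.")
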