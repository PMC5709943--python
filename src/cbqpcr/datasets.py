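"""Bundled worked-example data sets (hypothetical plate experiments).

Small illustrative tables used throughout the documentation and tests: a
single qPCR plate comparing two sample types with one gene of interest and
two reference genes, the per-replicate normalized values of a four-replicate
two-condition study, and two three-condition studies laid out for blocked
ANOVA (plates as blocks; individuals as blocks).  All values are
hypothetical teaching data, not measurements.
"""

from __future__ import annotations

import pandas as pd

from cbqpcr.io import ExperimentTable, ROLE_REFERENCE, ROLE_TARGET

# one plate: 2 sample types x 3 genes x 3 technical replicates, (E, Cq)
_SINGLE_PLATE = [
    # sample_type, gene, role, efficiency, cq, printed log10(E)*Cq
    ("A", "g", ROLE_TARGET, 1.844, 31.246, 8.303),
    ("A", "g", ROLE_TARGET, 1.843, 31.490, 8.360),
    ("A", "g", ROLE_TARGET, 1.836, 32.316, 8.527),
    ("B", "g", ROLE_TARGET, 1.839, 32.565, 8.647),
    ("B", "g", ROLE_TARGET, 1.834, 32.782, 8.631),
    ("B", "g", ROLE_TARGET, 1.823, 32.802, 8.555),
    ("A", "ref1", ROLE_REFERENCE, 1.905, 26.645, 7.458),
    ("A", "ref1", ROLE_REFERENCE, 1.886, 26.618, 7.335),
    ("A", "ref1", ROLE_REFERENCE, 1.868, 26.579, 7.215),
    ("B", "ref1", ROLE_REFERENCE, 1.918, 26.101, 7.382),
    ("B", "ref1", ROLE_REFERENCE, 1.906, 26.096, 7.309),
    ("B", "ref1", ROLE_REFERENCE, 1.915, 26.105, 7.368),
    ("A", "ref2", ROLE_REFERENCE, 1.900, 26.191, 7.298),
    ("A", "ref2", ROLE_REFERENCE, 1.881, 25.983, 7.129),
    ("A", "ref2", ROLE_REFERENCE, 1.879, 25.962, 7.113),
    ("B", "ref2", ROLE_REFERENCE, 1.890, 25.308, 6.998),
    ("B", "ref2", ROLE_REFERENCE, 1.883, 25.256, 6.940),
    ("B", "ref2", ROLE_REFERENCE, 1.911, 25.689, 7.223),
]


def single_plate_experiment() -> ExperimentTable:
    """One plate, two sample types, GOI ``g`` plus references ``ref1``/``ref2``.

    18 wells of raw (E, Cq) pairs; both sample types come from the same
    biological replicate ``r1``.
    """
    data = pd.DataFrame(
        {
            "replicate": "r1",
            "sample_type": [r[0] for r in _SINGLE_PLATE],
            "gene": [r[1] for r in _SINGLE_PLATE],
            "role": [r[2] for r in _SINGLE_PLATE],
            "plate": "plate1",
            "well": [f"w{i + 1}" for i in range(len(_SINGLE_PLATE))],
            "efficiency": [r[3] for r in _SINGLE_PLATE],
            "cq": [r[4] for r in _SINGLE_PLATE],
        }
    )
    return ExperimentTable(data=data, goi="g", refs=("ref1", "ref2"))


def single_plate_weighted() -> pd.DataFrame:
    """The same plate with the published per-well weighted values.

    The ``weighted_cq`` column carries the values as printed in the worked
    example (rounded to 3 decimals; the first B/``g`` well prints 8.647
    where its own (E, Cq) pair gives ≈8.616).  Downstream worked-example
    numbers follow this printed column.
    """
    return pd.DataFrame(
        {
            "replicate": "r1",
            "sample_type": [r[0] for r in _SINGLE_PLATE],
            "gene": [r[1] for r in _SINGLE_PLATE],
            "role": [r[2] for r in _SINGLE_PLATE],
            "weighted_cq": [r[5] for r in _SINGLE_PLATE],
        }
    )


def unpaired_delta_cq() -> pd.DataFrame:
    """ΔCq values for four biological replicates of two sample types.

    Replicate ``r1`` is the single-plate example above; the rest come from
    three further hypothetical plates.  Suitable for both the unpaired and
    (reading rows as pairs) the paired analysis.
    """
    return pd.DataFrame(
        {
            "replicate": ["r1", "r2", "r3", "r4"] * 2,
            "sample_type": ["A"] * 4 + ["B"] * 4,
            "delta_cq": [1.1387, 0.845, 0.499, 0.699, 1.4077, 1.291, 1.496, 1.172],
        }
    )


def plate_blocked_delta_cq() -> pd.DataFrame:
    """Three sample types x four replicates spread over two plates.

    Replicates ``r1``/``r2`` ran on plate 1 and ``r3``/``r4`` on plate 2;
    each plate holds every sample type, so the plate is a complete block.
    """
    return pd.DataFrame(
        {
            "replicate": ["r1", "r2", "r3", "r4"] * 3,
            "sample_type": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
            "plate": ["plate1", "plate1", "plate2", "plate2"] * 3,
            "delta_cq": [
                0.855, 0.711, 0.582, 0.699,
                1.203, 1.056, 0.890, 0.775,
                0.866, 0.799, 0.522, 0.669,
            ],
        }
    )


def individual_blocked_delta_cq() -> pd.DataFrame:
    """Three sample types paired within four individuals (one plate).

    The individual is the block: each biological replicate contributes one
    sample of every type, e.g. three organs per organism.
    """
    return pd.DataFrame(
        {
            "replicate": ["r1", "r2", "r3", "r4"] * 3,
            "sample_type": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
            "delta_cq": [
                0.855, 0.845, 0.499, 0.699,
                1.408, 1.056, 1.291, 1.172,
                0.866, 0.799, 0.532, 0.707,
            ],
        }
    )
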