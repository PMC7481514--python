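"""Randomized complete block design (RCBD) layout for the greenhouse trial.

The default trial mirrors a two-N-level ryegrass screen: G genotypes × T
nitrogen treatments × R replicates, laid out in conveyor rows of fixed
capacity.  Each replicate occupies a contiguous band of rows in which the
treatments alternate row by row, and genotypes are randomized independently
within every treatment row — so every (genotype, treatment, replicate)
combination occurs exactly once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import InvalidArgumentError

DEFAULT_TREATMENTS = (0.5, 5.0)  # mM elemental N in the nutrient solution


def generate_design(
    n_genotypes: int = 76,
    treatments: tuple[float, ...] = DEFAULT_TREATMENTS,
    n_replicates: int = 4,
    row_capacity: int = 38,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an RCBD trial table.

    Returns a DataFrame with columns ``pot_id, genotype, treatment,
    replicate, row_index, position_in_row``.  Randomization is a pure
    function of the arguments and ``seed``.
    """
    n_treatments = len(treatments)
    if n_genotypes < 1 or n_treatments < 1 or n_replicates < 1 or row_capacity < 1:
        raise InvalidArgumentError("all design counts must be >= 1")
    if len(set(treatments)) != n_treatments:
        raise InvalidArgumentError("treatment levels must be distinct")

    rng = np.random.default_rng(seed)
    genotypes = np.arange(1, n_genotypes + 1)
    rows_per_treatment = -(-n_genotypes // row_capacity)  # ceil

    records = []
    row_index = 0
    for rep in range(1, n_replicates + 1):
        # within a replicate band, treatments alternate between rows
        order: list[tuple[float, np.ndarray]] = []
        for r in range(rows_per_treatment):
            for trt in treatments:
                order.append((trt, r))
        shuffled = {trt: rng.permutation(genotypes) for trt in treatments}
        for trt, chunk in order:
            block = shuffled[trt][chunk * row_capacity : (chunk + 1) * row_capacity]
            for pos, geno in enumerate(block, start=1):
                records.append(
                    {
                        "genotype": int(geno),
                        "treatment": float(trt),
                        "replicate": rep,
                        "row_index": row_index,
                        "position_in_row": pos,
                    }
                )
            row_index += 1

    design = pd.DataFrame.from_records(records)
    design.insert(
        0,
        "pot_id",
        [
            f"P{i:04d}" for i in range(1, len(design) + 1)
        ],
    )
    return design


def validate_design(design: pd.DataFrame) -> None:
    """Check RCBD completeness; raises InvalidArgumentError on violation."""
    cells = design.groupby(["genotype", "treatment", "replicate"]).size()
    if (cells != 1).any():
        raise InvalidArgumentError("design is not a complete RCBD")
    g = design["genotype"].nunique()
    t = design["treatment"].nunique()
    r = design["replicate"].nunique()
    if len(design) != g * t * r:
        raise InvalidArgumentError("pot count does not equal G x T x R")
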