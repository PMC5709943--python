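"""Classical single-reference relative-quantification formulas.

These are the textbook fold-change estimators — ``2^(−ΔΔCq)`` assuming
perfect doubling, and the efficiency-corrected ratio
``E_GOI^(−ΔCq_GOI) / E_REF^(−ΔCq_REF)`` with one gene-wise constant
efficiency per gene.  They are kept solely as independent cross-checks:
on data meeting their assumptions (single reference gene; constant or
ideal efficiencies) the common-base pipeline must reproduce them exactly,
and the test suite asserts that it does.  They are not analysis entry
points and support neither multiple reference genes nor per-well
efficiencies.
"""

from __future__ import annotations

import numpy as np

from cbqpcr.io import ExperimentTable


def _mean_cq(table: ExperimentTable, sample_type: str, gene: str) -> float:
    data = table.data
    sel = (data["sample_type"] == sample_type) & (data["gene"] == gene)
    if not sel.any():
        raise ValueError(f"no wells for ({sample_type!r}, {gene!r})")
    return float(data.loc[sel, "cq"].mean())


def _single_ref(table: ExperimentTable) -> str:
    if len(table.refs) != 1:
        raise ValueError(
            "classical formulas support exactly one reference gene, got "
            f"{list(table.refs)}"
        )
    return table.refs[0]


def livak_ratio(table: ExperimentTable, type_a: str, type_b: str) -> float:
    """Fold change ``2^(−ΔΔCq)`` from raw mean Cq values (assumes E = 2)."""
    ref = _single_ref(table)
    dd = (
        _mean_cq(table, type_a, table.goi) - _mean_cq(table, type_a, ref)
    ) - (_mean_cq(table, type_b, table.goi) - _mean_cq(table, type_b, ref))
    return float(2.0 ** (-dd))


def pfaffl_ratio(
    table: ExperimentTable,
    type_a: str,
    type_b: str,
    e_goi: float | None = None,
    e_ref: float | None = None,
) -> float:
    """Efficiency-corrected fold change with gene-wise constant efficiencies.

    ``E_GOI^(−(Cq_GOI,A − Cq_GOI,B)) / E_REF^(−(Cq_REF,A − Cq_REF,B))``.
    Efficiencies default to the mean observed efficiency per gene across
    all wells of the experiment.
    """
    ref = _single_ref(table)
    data = table.data
    if e_goi is None:
        e_goi = float(data.loc[data["gene"] == table.goi, "efficiency"].mean())
    if e_ref is None:
        e_ref = float(data.loc[data["gene"] == ref, "efficiency"].mean())
    d_goi = _mean_cq(table, type_a, table.goi) - _mean_cq(table, type_b, table.goi)
    d_ref = _mean_cq(table, type_a, ref) - _mean_cq(table, type_b, ref)
    return float(np.power(e_goi, -d_goi) / np.power(e_ref, -d_ref))
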