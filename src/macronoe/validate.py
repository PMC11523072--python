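"""Model/Results interface for NOE validation of a conformer ensemble.

:class:`NOEValidation` bundles an ensemble, a molecular graph and a
restraint table; :meth:`NOEValidation.fit` back-calculates every
restraint (after optional prochiral assignment), attaches region and
bond-separation annotations, estimates split errors, and returns a
:class:`NOEValidationResults` carrying per-restraint estimates, their
uncertainties and summary scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import noe as _noe
from . import restraints as _restraints
from .molsys import MoleculeGraph, bond_separation, classify_region, detect_macrocycle

__all__ = ["NOEValidation", "NOEValidationResults"]


class NOEValidation:
    """NOE upper-bound validation model for one conformer ensemble.

    Parameters
    ----------
    ensemble:
        :class:`macronoe.noe.ConformerEnsemble` (coordinates in nm).
    graph:
        :class:`macronoe.molsys.MoleculeGraph` matching the ensemble's
        atom order.
    table:
        :class:`macronoe.restraints.RestraintTable` of upper bounds.
    threshold:
        Violation threshold (nm) for the fraction score; strict
        inequality.
    n_segments:
        Number of contiguous blocks for the split-error estimate.
    assign_prochiral:
        Whether to optimize prochiral assignments against this ensemble
        before back-calculation.
    """

    def __init__(self, ensemble, graph: MoleculeGraph, table,
                 threshold: float = _noe.VIOLATION_THRESHOLD_NM,
                 n_segments: int = 5, assign_prochiral: bool = True,
                 min_ring_size: int = 12):
        self.ensemble = ensemble
        self.graph = graph
        self.table = table
        self.threshold = threshold
        self.n_segments = n_segments
        self.do_assign_prochiral = assign_prochiral
        self.min_ring_size = min_ring_size

    def fit(self) -> "NOEValidationResults":
        table = self.table
        if self.do_assign_prochiral:
            table = _restraints.assign_prochiral(table, self.ensemble, self.graph)
        macro = detect_macrocycle(self.graph, self.min_ring_size)
        results = []
        for r in table:
            d_avg = _noe.r6_average(self.ensemble, r)
            viol = _noe.violation(d_avg, r.d_ref)
            anchors = r.heavy_anchors(self.graph)
            results.append(_noe.NOEResult(
                restraint_id=r.id, d_avg=d_avg, d_ref=r.d_ref, violation=viol,
                region=classify_region(self.graph, anchors, macro),
                bond_separation=bond_separation(self.graph, *anchors)))
        n_window = self.ensemble.window_frames().shape[0]
        if n_window >= self.n_segments:
            stds, rms = _noe.split_errors(self.ensemble, table, self.n_segments)
            for res in results:
                res.split_std = stds[res.restraint_id]
        else:
            rms = float("nan")
        return NOEValidationResults(
            model=self, table=table, results=results, rms_split_std=rms)


@dataclass
class NOEValidationResults:
    """Per-restraint NOE estimates with uncertainties and summary scores."""

    model: NOEValidation
    table: object
    results: list
    rms_split_std: float

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "id": r.restraint_id,
            "d_avg_nm": r.d_avg,
            "d_ref_nm": r.d_ref,
            "violation_nm": r.violation,
            "split_std_nm": r.split_std,
            "region": r.region,
            "bond_separation": r.bond_separation,
        } for r in self.results])

    @property
    def fraction_violations(self) -> float:
        return _noe.fraction_violations(self.results, self.model.threshold)

    def fraction_by_region(self) -> dict[str, float]:
        out = {}
        for region in ("macrocyclic", "extracyclic", "mixed"):
            sub = [r for r in self.results if r.region == region]
            if sub:
                out[region] = _noe.fraction_violations(sub, self.model.threshold)
        return out

    def summary(self) -> str:
        df = self.frame
        lines = ["NOE upper-bound validation", "=" * 62]
        lines.append(f"restraints: {len(df)}   frames: {self.model.ensemble.n_frames}"
                     f"   window: {self.model.ensemble.window:g}")
        lines.append(f"violation threshold: {self.model.threshold:g} nm (strict)")
        lines.append(f"fraction of violations: {self.fraction_violations:.3f}")
        for region, frac in self.fraction_by_region().items():
            lines.append(f"  {region:<12s} {frac:.3f}")
        lines.append(f"rms split error: {self.rms_split_std:.4f} nm"
                     f" ({self.model.n_segments} segments)")
        lines.append("-" * 62)
        with pd.option_context("display.max_rows", None, "display.width", 100):
            lines.append(df.to_string(index=False,
                                      float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def to_tsv(self, path):
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_json_summary(self, path=None):
        payload = {
            "n_restraints": len(self.results),
            "threshold_nm": self.model.threshold,
            "fraction_violations": self.fraction_violations,
            "fraction_by_region": self.fraction_by_region(),
            "rms_split_std_nm": self.rms_split_std,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1)
        return payload
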