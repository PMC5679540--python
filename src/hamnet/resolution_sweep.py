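"""Multi-resolution analysis: run the detector across a grid of weight
thresholds and report community count, modularity, and (optionally) NMI
against a reference partition at each threshold."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .graph import Graph, Partition
from .quality import nmi
from .supernode_phase import run_ham


@dataclass
class SweepRow:
    w_threshold: float
    n_communities: int
    q: float
    nmi: Optional[float] = None


def default_grid(start: float = 0.0, stop: float = 1.0, step: float = 0.01) -> list[float]:
    """Inclusive threshold grid; rounded to the step's precision to avoid
    floating-point drift in the printed thresholds."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((stop - start) / step))
    decimals = max(0, len(str(step).split(".")[-1])) if "." in str(step) else 0
    return [round(start + k * step, decimals + 2) for k in range(n + 1)]


def threshold_sweep(
    g: Graph,
    measure: str = "min",
    thresholds: Sequence[float] = (),
    reference: Optional[Partition] = None,
    epsilon: float = 0.0,
) -> list[SweepRow]:
    """One deterministic detection run per threshold, in ascending order."""
    thresholds = list(thresholds) or default_grid()
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    rows: list[SweepRow] = []
    for w in thresholds:
        res = run_ham(g, measure=measure, w_threshold=w, epsilon=epsilon)
        part = res.final_partition
        score = None
        if reference is not None:
            score = nmi(part, reference)
        rows.append(SweepRow(w, part.n_communities, res.final_q, score))
    return rows


def write_sweep_csv(rows: Iterable[SweepRow], path) -> None:
    rows = list(rows)
    with_nmi = any(r.nmi is not None for r in rows)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("threshold,n_communities,Q" + (",nmi" if with_nmi else "") + "\n")
        for r in rows:
            line = f"{r.w_threshold},{r.n_communities},{r.q:.10g}"
            if with_nmi:
                line += f",{r.nmi:.10g}" if r.nmi is not None else ","
            fh.write(line + "\n")
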