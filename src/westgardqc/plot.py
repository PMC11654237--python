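"""Static Levey-Jennings chart export (optional; needs matplotlib)."""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .model import ControlSpec, QCResult
from .rules import RunDecision


def levey_jennings(
    results: Iterable[QCResult],
    spec: ControlSpec,
    path,
    *,
    decisions: Optional[Sequence[RunDecision]] = None,
    title: Optional[str] = None,
) -> None:
    """Save a Levey-Jennings chart for one analyte/level to ``path``.

    Horizontal guides at the target mean and +-1/2/3 SD; rejected runs
    (when ``decisions`` is given) are marked in red.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    points = sorted(
        (r for r in results if (r.analyte_id, r.level_id) == (spec.analyte_id, spec.level_id)),
        key=lambda r: r.run_index,
    )
    runs = [r.run_index for r in points]
    values = [r.value for r in points]
    rejected = {
        d.run_index for d in (decisions or []) if d.status == "reject"
    }

    fig, ax = plt.subplots(figsize=(9, 3.5))
    for k in (1, 2, 3):
        for sign in (1, -1):
            ax.axhline(
                spec.target_mean + sign * k * spec.target_sd,
                color="grey", lw=0.6, ls=":" if k < 3 else "--",
            )
    ax.axhline(spec.target_mean, color="black", lw=0.8)
    ax.plot(runs, values, "-o", ms=3, lw=0.8, color="tab:blue")
    bad = [(r, v) for r, v in zip(runs, values) if r in rejected]
    if bad:
        ax.plot(*zip(*bad), "o", ms=5, color="tab:red", label="rejected run")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("run")
    ax.set_ylabel(f"value (g/L)")
    ax.set_title(title or f"{spec.analyte_id} {spec.level_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
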