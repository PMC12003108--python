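"""Report writers: results tables, machine-readable exports, run manifests,
and optional static figures.

Machine outputs (CSV/JSON) carry full precision; the human-readable results
table rounds the way the published table does (costs to whole CNY, QALYs and
life-years to two decimals).  All writers are deterministic: re-rendering
identical inputs produces byte-identical files (the manifest's timestamp is
the only time-dependent output).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass

from .cea import CEAResult
from .params import ParameterSet, parameters_to_dict

__all__ = ["render_table2", "cea_result_json", "RunManifest", "config_digest"]


def _fmt_cost(v: float) -> str:
    return f"{v:,.0f}"


def _fmt2(v: float) -> str:
    return f"{v:.2f}"


def _block(label: str, res: CEAResult) -> list[list[str]]:
    i, c = res.intervention, res.comparator
    return [
        [label, "", "", "", "", "", "", ""],
        ["Control", _fmt_cost(c.total_cost), _fmt2(c.total_qaly), _fmt2(c.total_ly),
         "", "", "", ""],
        ["Argatroban", _fmt_cost(i.total_cost), _fmt2(i.total_qaly), _fmt2(i.total_ly),
         _fmt_cost(res.delta_cost), _fmt2(res.delta_qaly), _fmt2(res.delta_ly),
         _fmt_cost(res.icer)],
    ]


def render_table2(base: CEAResult, scenarios: dict[str, CEAResult] | None = None) -> str:
    """Results table in the published presentation shape: one two-row block
    per analysis (base case first, then named scenarios)."""
    header = ["", "Total cost (CNY)", "Total effectiveness (QALY)",
              "Total effectiveness (LY)", "Incremental cost (CNY)",
              "Incremental effectiveness (QALY)", "Incremental effectiveness (LY)",
              "ICER (CNY per QALY)"]
    rows = [header]
    rows += _block("Base case", base)
    for name, res in (scenarios or {}).items():
        rows += _block(name, res)
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = ["\t".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
             for row in rows]
    return "\n".join(lines) + "\n"


def cea_result_json(res: CEAResult) -> str:
    """Full-precision JSON record of a two-arm comparison."""
    return json.dumps(res.to_record(), indent=2, sort_keys=True)


def config_digest(params: ParameterSet) -> str:
    """SHA-256 over the canonical serialized inputs; changes iff any value does."""
    payload = json.dumps(parameters_to_dict(params), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    subcommand: str
    config_digest: str
    seed: int | None
    package_version: str
    outputs: list[str]
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S%z")

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# optional static figures
# ---------------------------------------------------------------------------

def plot_ce_plane(psa, wtp: float, path) -> None:
    """Incremental cost vs incremental effectiveness scatter with the WTP line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=4, alpha=0.3)
    xs = [min(psa.delta_qaly.min(), 0), max(psa.delta_qaly.max(), 0)]
    ax.plot(xs, [wtp * x for x in xs], "k--", lw=1, label=f"WTP = {wtp:,.0f} CNY/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental effectiveness (QALY)")
    ax.set_ylabel("Incremental cost (CNY)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(psa, path) -> None:
    """Cost-effectiveness acceptability curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(psa.wtp_grid, psa.ceac)
    ax.set_xlabel("Willingness to pay (CNY per QALY)")
    ax.set_ylabel("P(argatroban cost-effective)")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(entries, base_icer: float, path, top: int = 15) -> None:
    """Horizontal tornado bars of ICER ranges, widest on top."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = [e for e in entries if e.width > 0][:top]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(shown) + 1.5))
    for y, e in enumerate(reversed(shown)):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(y, hi - lo, left=lo, height=0.6)
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in reversed(shown)], fontsize=8)
    ax.set_xlabel("ICER (CNY per QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
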