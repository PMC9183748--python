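"""Risk-profile assembly and report rendering.

The four deterioration channels — mechanical (RH excursions outside the
historical-climate band), chemical (expected lifetime below the planning
horizon, one value per paper type), mould (days above the germination
isopleth) and insect (egg-laying relative to the annual maximum) — are each
expressed as a Risk Index in percent of time and presented side by side on
a radar plot; they are deliberately not collapsed into a single scalar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RiskProfile", "assemble_risk_profile", "render_report"]


@dataclass
class RiskProfile:
    """The yearly Risk Index profile for one collection."""

    collection_label: str
    window_label: str
    mechanical_RI: float
    chemical_RI: dict[str, float]  # per paper type
    mould_RI: float
    insect_RI: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.as_channels().items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"risk index {name} = {v} outside [0, 100]")

    def as_channels(self) -> dict[str, float]:
        out = {"mechanical": self.mechanical_RI}
        out.update({f"chemical ({p})": v for p, v in self.chemical_RI.items()})
        out["mould"] = self.mould_RI
        out["insect"] = self.insect_RI
        return out

    def to_dict(self) -> dict:
        return {
            "collection": self.collection_label,
            "window": self.window_label,
            "risk_index_percent": self.as_channels(),
            "provenance": self.provenance,
        }


def assemble_risk_profile(
    collection_label: str,
    mechanical: tuple[str, float],
    chemical: tuple[str, dict[str, float]],
    mould: tuple[str, float],
    insect: tuple[str, float],
    provenance: dict | None = None,
) -> RiskProfile:
    """Combine the four channel outputs into a profile.

    Each channel arrives as (window_label, value); all four must have been
    computed on the same yearly window — a mismatch is an error, never
    silently reconciled. Pure assembly: nothing is recomputed here.
    """
    labels = {mechanical[0], chemical[0], mould[0], insect[0]}
    if len(labels) != 1:
        raise ValueError(f"channel windows disagree: {sorted(labels)}")
    return RiskProfile(
        collection_label=collection_label,
        window_label=mechanical[0],
        mechanical_RI=mechanical[1],
        chemical_RI=chemical[1],
        mould_RI=mould[1],
        insect_RI=insect[1],
        provenance=provenance or {},
    )


def _radar(ax, profile: RiskProfile) -> None:
    channels = profile.as_channels()
    labels = list(channels)
    values = list(channels.values())
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False).tolist()
    values += values[:1]
    angles += angles[:1]
    ax.plot(angles, values, "o-", lw=1.5)
    ax.fill(angles, values, alpha=0.25)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_ylim(0, 100)
    ax.set_title(f"Risk Index (%) — {profile.collection_label}", fontsize=10)


def render_report(
    profiles: list[RiskProfile],
    out_dir: str | Path,
    tables: dict[str, pd.DataFrame] | None = None,
    figures: dict | None = None,
) -> dict:
    """Write the report bundle: JSON summary, tables and figures.

    The JSON summary and delimited-text tables are deterministic functions
    of their inputs (regeneration on identical inputs is byte-identical);
    figures are rendered with a fixed style. Returns a manifest of the
    files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"summary": "risk_profile.json", "tables": [], "figures": []}

    summary = [p.to_dict() for p in profiles]
    (out / "risk_profile.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )

    for name, df in (tables or {}).items():
        path = out / f"{name}.csv"
        df.to_csv(path, float_format="%.6g")
        manifest["tables"].append(path.name)

    fig, axes = plt.subplots(
        1, max(1, len(profiles)), figsize=(5.0 * max(1, len(profiles)), 4.5),
        subplot_kw={"projection": "polar"},
    )
    for ax, prof in zip(np.atleast_1d(axes).ravel(), profiles):
        _radar(ax, prof)
    fig.tight_layout()
    fig.savefig(out / "risk_radar.png", dpi=120)
    plt.close(fig)
    manifest["figures"].append("risk_radar.png")

    for name, fig_obj in (figures or {}).items():
        path = out / f"{name}.png"
        fig_obj.savefig(path, dpi=120)
        plt.close(fig_obj)
        manifest["figures"].append(path.name)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
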