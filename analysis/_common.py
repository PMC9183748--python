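"""Shared plumbing for the numbered analysis drivers: the demo campaign is
generated once (deterministically) and reused by every later step."""

from pathlib import Path

from librisk import (
    ClimateScenario,
    generate_climate,
    read_hygro_series,
    write_hygro_series,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
CAMPAIGN = RESULTS / "campaign"

SEED = 11
START = "2019-08-01"
SPAN_DAYS = 380.0
STEP_MINUTES = 60.0

#: collection label → (scenario preset, representative probe id)
COLLECTIONS = {"Ancient": ("shelved", "RHT3"), "Modern": ("ventilated", "RHT5")}


def build_campaign():
    """Generate (or reload) the demo campaign: a quiet 'shelved' area with
    three levels (Ancient) and a more ventilated single probe (Modern)."""
    CAMPAIGN.mkdir(parents=True, exist_ok=True)
    paths = {}
    if not (CAMPAIGN / "RHT1.csv").exists():
        shelved = ClimateScenario.preset("shelved", seed=SEED, n_levels=3)
        probes, outdoor = generate_climate(
            shelved, start=START, span_days=SPAN_DAYS, step_minutes=STEP_MINUTES
        )
        vent = ClimateScenario.preset("ventilated", seed=SEED + 1, n_levels=1)
        vent_probes, _ = generate_climate(
            vent, start=START, span_days=SPAN_DAYS, step_minutes=STEP_MINUTES
        )
        probes["RHT5"] = vent_probes["RHT1"]
        probes["RHT5"].probe_id = "RHT5"
        for pid, s in {**probes, "outdoor": outdoor}.items():
            write_hygro_series(s, CAMPAIGN / f"{pid}.csv")
    for p in sorted(CAMPAIGN.glob("*.csv")):
        paths[p.stem] = p
    return {pid: read_hygro_series(path) for pid, path in paths.items()}
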