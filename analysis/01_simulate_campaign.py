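"""Generate the synthetic monitoring campaign used by every later step.

One year-plus of hourly indoor T/RH for a quiet multi-level repository area
(three probes, 'Ancient' collection) and a more ventilated area (one probe,
'Modern' collection), plus the outdoor reference. Writes delimited text
under results/campaign/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import CAMPAIGN, build_campaign

series = build_campaign()
print(f"campaign in {CAMPAIGN}:")
for pid, s in series.items():
    t0, t1 = s.span
    print(f"  {pid}: {len(s)} records, {t0.date()} .. {t1.date()}, "
          f"T median {s.data['T'].median():.1f} degC, "
          f"RH median {s.data['RH'].median():.1f} %")
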