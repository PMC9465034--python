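"""Outbreak analysis over a growing moth-count series.

Counts grow 25% per day with Poisson noise. The engine works in 7-day
cycles: within cycle 1 every day's count is compared with the cardinal
(day-1) count through the increasing rate IR; from cycle 2 the day-on-day
rate DIR and cycle-on-cycle rate CIR take over. Each cycle gets a density,
a pest increasing rate (PIR) against cycle 1, and an outbreak level 1-5;
each day gets a warning color (blue 0-100%, orange 100-300%, red >300%).
"""

from pestwatch.synthgen import CountSeriesSpec, make_count_series
from pestwatch.warning import analyze

counts = make_count_series(CountSeriesSpec(n_days=21, base_count=4,
                                           daily_growth=1.25, noise=1.0,
                                           seed=3))
report = analyze(counts)

print("day  count  cycle  IR%      DIR%     CIR%     warning")
for d in report.days:
    def fmt(r):
        return "   --  " if r is None or not r.defined else f"{r.value:7.1f}"
    print(f"{d.date:>5} {d.count:5d} {d.cycle:5d} {fmt(d.ir)} {fmt(d.dir)} "
          f"{fmt(d.cir)}  {d.color}")

print("\ncycle  density  PIR%     outbreak level")
for c in report.cycles:
    pir = "--" if not c.pir.defined else f"{c.pir.value:.1f}"
    print(f"{c.cycle:5d} {c.density:8.0f} {pir:>8}  level {c.level}")
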