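"""Scale PSMC output into an effective-size trajectory and measure declines.

A three-epoch bottleneck history (peak one million individuals 60-90 kyr
before present) is encoded into a mock PSMC output file, parsed back, and
scaled to real units with a 12% false-negative-rate correction estimated
from a planted variant dropout.
"""

from declinomics import demog, synthio

MU = 1.2e-8  # per-site per-generation; supply your organism's estimate
GEN_TIME = 10.0  # years

# FNR from a doubled-input recount, emulated by dropping 12% of variants
n_total = 1_000_000
n_low = synthio.dropout_retained_count(n_total, synthio.DropoutSpec(0.12, seed=3))
fnr = demog.estimate_fnr(n_total, n_low)
print(f"estimated FNR = {100 * fnr.fnr:.1f}% ({n_total - n_low:,} variants lost)")

history = synthio.NeHistory(
    epochs=[(0.0, 109_000.0), (60_000.0, 1_000_000.0), (90_000.0, 100_000.0)],
    mu=MU,
    gen_time=GEN_TIME,
)
text = synthio.gen_mock_psmc_file(history, n_intervals=24, theta0=0.05)
raw = demog.parse_psmc(text)
traj = demog.scale_psmc_output(raw, mu=MU, gen_time=GEN_TIME, fnr=fnr.fnr)

peak = traj.ne.max()
ne20k = demog.ne_at(traj, 20_000.0)
print(f"N0 = {traj.n0:,.0f}; peak Ne = {peak:,.0f}; Ne at 20 kybp = {ne20k:,.0f}")
print(f"peak -> census(1,000): {demog.percent_decline(peak, 1_000):.1f}% decline")
print(f"20 kybp -> census(1,000): {demog.percent_decline(ne20k, 1_000):.1f}% decline")
# The FNR correction scales theta0 (hence N0, Ne and times) by 1/(1-FNR);
# the decline percentages compare trajectory values to a modern census size.
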