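"""Readout-rate arithmetic of the data-acquisition design.

A binary strip ASIC cycled at 26 MHz reading up to 8 channels per cycle
bounds the proton rate the instrument can track; the subsystem data
rates are checked for internal consistency.
"""

from protonct import daq_budget_check

rep = daq_budget_check()
print(f"readout cycle: {rep.cycle_ns_exact:.2f} ns (quoted {rep.cycle_ns} ns)")
print(f"max trackable proton rate: {rep.max_protons_per_s:.0e} protons/s")
print(f"tracker data rate: {rep.tracker_gbps:.0f} Gb/s, "
      f"range telescope: {rep.rt_gbps:.0f} Gb/s")
print(f"subsystem sum: {rep.combined_gbps_sum:.0f} Gb/s vs quoted combined "
      f"{rep.combined_gbps_printed:.0f} Gb/s "
      f"(discrepancy {rep.discrepancy_gbps:+.0f} Gb/s, informational)")
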