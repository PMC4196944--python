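"""Quality-trim a batch of simulated reads and report the QC summary.

Simulates 2,000 100-bp reads of which 4% are planted failures (uniformly low
quality, embedded Ns, or a usable stretch shorter than 30 bp), trims each
read with the running-sum criterion at Phred 20, and drops reads that come
out shorter than 30 bp or still contain an N.
"""

from poolsweep import SimulationConfig, TrimConfig, simulate_fastq, trim_and_filter

cfg = SimulationConfig(seed=1)
reads, truth = simulate_fastq(cfg)
kept, summary = trim_and_filter(reads, TrimConfig())

print(f"input reads          {summary.n_input}")
print(f"kept after trim+QC   {summary.n_kept}")
print(f"kept fraction        {summary.kept_fraction:.3f}  (planted clean fraction {truth.expected_kept_fraction:.3f})")
print(f"mean retained length {summary.mean_retained_length:.1f} bp")
# The kept fraction tracks the planted 96% clean reads; retained length stays
# near the 100-bp read length because good reads carry no low-quality tails.
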