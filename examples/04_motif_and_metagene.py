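"""Sequence-context and 3'-positional diagnostics of called edits.

A poly(A)-binding reporter deposits edits close to transcript 3' ends at
chemistry-consistent dinucleotides (TA for the A>G enzyme). Both biases
are quality checks: their absence would indicate spurious calls.
"""

from rlpkit import (
    SimulationTruth, call_events, designated_transcripts, extract_context,
    frequency_matrix, make_transcriptome, metagene_polyA_density,
    simulate_bulk,
)

truth = SimulationTruth(seed=4, n_genes=200, frac_compartment=1.0)
models, genome = make_transcriptome(200, seed=4)
sim = simulate_bulk(truth, models, genome)
events = call_events(sim.induced, sim.controls, models, chemistry="A>G")

hist, n_far = metagene_polyA_density(events, designated_transcripts(models),
                                     window=1000, bin_size=50)
mass = hist[(hist.bin_start >= 50) & (hist.bin_end <= 250)].density.sum()
print(f"{len(events)} events; {mass:.1%} of metagene density lies 50-250 nt "
      f"upstream of the poly(A) site ({n_far} events beyond 1 kb)")

ctx = extract_context(genome, events, flank=10)
freq = frequency_matrix(ctx)
print(f"center base (position 0): {freq.loc[0].idxmax()} "
      f"at frequency {freq.loc[0].max():.2f} (the edited A)")
print(f"position -1 modal base: {freq.loc[-1].idxmax()} "
      f"at frequency {freq.loc[-1].max():.2f} "
      "(T at -1 + A at 0 = the TA dinucleotide preference of the enzyme)")
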