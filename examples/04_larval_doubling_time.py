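"""Larval germ-cell doubling time from exponential fits.

Two primordial germ cells proliferate exponentially during larval stages;
counts at 0, 17 and 21 h after feeding, fit log2-linearly, return the
doubling time. A slow-cycling mutant (8.1 h vs 6.1 h) is resolved cleanly
even with Poisson counting noise.
"""

from spckinetics import kinetics, popsim

TIMES = (0.0, 17.0, 21.0)

for name, td, seed in (("wild-type-like", 6.1, 1), ("slow mutant", 8.1, 2)):
    exact = popsim.simulate_larval_growth(2, td, TIMES, noise="none")
    noisy = popsim.simulate_larval_growth(2, td, TIMES, noise="poisson", seed=seed)
    fit_exact = kinetics.fit_doubling_time(TIMES, exact)
    fit_noisy = kinetics.fit_doubling_time(TIMES, noisy)
    print(f"{name:15s}: counts {noisy.astype(int).tolist()} -> "
          f"Td = {fit_noisy.doubling_time:.2f} h (noise-free fit "
          f"{fit_exact.doubling_time:.4f} h, truth {td} h)")

print(
    "\nNoise-free counts return the generating doubling time exactly;\n"
    "Poisson-noised counts scatter around it."
)
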