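"""Jet-expansion stage of a ship exhaust plume.

Computes the first-second dilution ratio of a ROPAX ferry stack under each
monitored harbor event's wind, the in-plume temperature after the stage, and
the fraction of particles that survive coagulation during the expansion.
"""

from shipplume import (
    StackSpec,
    coagulation_fraction_remaining,
    first_stage_dilution_ratio,
    initial_plume_temperature,
    list_events,
    make_event,
)

stack = StackSpec()  # 0.55 m^2 pipe, 25 m/s exit, 580 K exhaust

print("event        U (m/s)   DR    T_plume (K)  coag. survival")
for event_id in list_events():
    ev = make_event(event_id)
    dr = first_stage_dilution_ratio(stack, ev.wind_speed)
    t_p = initial_plume_temperature(ev.air_temperature, stack.exhaust_temperature, dr)
    surv = coagulation_fraction_remaining(5e6, stack, wind_speed=ev.wind_speed)
    print(f"{event_id}  {ev.wind_speed:5.1f}  {dr:6.2f}  {t_p:9.1f}  {surv:12.2f}")

print(
    "\nDR ~ 8 for every event: the stack exhaust is diluted eightfold within"
    "\n1 s, which also pulls a 580 K exhaust down to ~320 K. Coagulation"
    "\nremoves only 6-18% of particles during the expansion at typical winds,"
    "\nbut more when weak wind keeps the plume concentrated."
)
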