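"""Deliberately naive day-by-day coverage oracle.

Loops over follow-up days maintaining one remaining-supply counter per drug:
fills deposit their days' supply into the drug's bank on the fill day; on a
facility day nothing is consumed; on any other day every drug with a
positive bank consumes one day and the day is covered if any did.  This is
independent of the interval-based engine and serves as its exact reference.
"""

from collections import defaultdict

import numpy as np

from artgaps.exposure import COVERED, FACILITY, GAP


def day_classes_oracle(fills, stay_intervals, window_length):
    """fills: (day, drug_id, days_supply); stays: inclusive (admit, discharge)."""
    facility = set()
    for a, b in stay_intervals:
        facility.update(d for d in range(max(1, a), min(window_length, b) + 1))
    deposits = defaultdict(list)
    for day, drug, supply in fills:
        if 1 <= day <= window_length:
            deposits[day].append((drug, supply))
    bank: dict[str, int] = defaultdict(int)
    out = np.empty(window_length, dtype=np.int8)
    for d in range(1, window_length + 1):
        for drug, supply in deposits.get(d, ()):
            bank[drug] += supply
        if d in facility:
            out[d - 1] = FACILITY
            continue
        covered = False
        for drug in bank:
            if bank[drug] > 0:
                bank[drug] -= 1
                covered = True
        out[d - 1] = COVERED if covered else GAP
    return out
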