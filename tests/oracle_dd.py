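"""Brute-force re-implementation of the estimator for cross-checking.

Explicit Python loops over observation records, no pandas group-bys or
vectorization, kept deliberately independent of the package internals:
only the phase calendar object is shared (it is pure data).
"""


def months_of(calendar, phase_ids):
    months = []
    for phase in calendar.phases:
        if phase.phase_id in phase_ids:
            y, m = phase.first_month
            while (y, m) <= phase.last_month:
                months.append((y, m))
                if m == 12:
                    y, m = y + 1, 1
                else:
                    m += 1
    return months


def brute_phase_mean(records, indicator_id, arm_zones, months,
                     pooling="pooled"):
    """records: iterable of (zone, indicator, (year, month), value|None)."""
    month_set = set(months)
    if pooling == "pooled":
        total, n = 0.0, 0
        for zone, ind, ym, value in records:
            if (
                ind == indicator_id
                and zone in arm_zones
                and ym in month_set
                and value is not None
            ):
                total += value
                n += 1
        return total / n if n else None
    # zone-mean: average within each zone first
    per_zone: dict = {}
    for zone, ind, ym, value in records:
        if (
            ind == indicator_id
            and zone in arm_zones
            and ym in month_set
            and value is not None
        ):
            per_zone.setdefault(zone, []).append(value)
    if not per_zone:
        return None
    zone_means = [sum(v) / len(v) for v in per_zone.values()]
    return sum(zone_means) / len(zone_means)


def brute_impact(records, indicator_id, pro_zones, non_zones,
                 before_months, since_months, epsilon=1e-9,
                 pooling="pooled"):
    """Return (double_difference, percent_impact or None)."""
    bp = brute_phase_mean(records, indicator_id, pro_zones, before_months,
                          pooling)
    sp = brute_phase_mean(records, indicator_id, pro_zones, since_months,
                          pooling)
    bn = brute_phase_mean(records, indicator_id, non_zones, before_months,
                          pooling)
    sn = brute_phase_mean(records, indicator_id, non_zones, since_months,
                          pooling)
    if None in (bp, sp, bn, sn):
        return None, None
    delta_pro = sp - bp
    delta_non = sn - bn
    dd = delta_pro - delta_non
    if abs(delta_non) < epsilon:
        return dd, None
    return dd, delta_pro / delta_non - 1.0
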