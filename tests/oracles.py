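"""Deliberately naive re-implementations of the diet-seasonality
indicators, used as independent oracles by the unit and acceptance tests.
They share no code with the package internals."""

import numpy as np


def oracle_indicators(table, rep_ids):
    """Deliberately naive loops, independent of the package internals."""
    from math import comb, log

    counts = table.counts.loc[rep_ids].values.astype(float)
    meta = table.sample_meta.loc[rep_ids]
    out = {}
    for se in ("summer", "winter"):
        in_season = (meta["season"] == se).values
        A = counts[in_season]
        qs = A.sum(axis=0) / A.sum()
        qmin = min(q for q in qs if q > 0)
        dvals = []
        for row in A:
            p = row / row.sum()
            d = sum(pi * log(pi / qi) for pi, qi in zip(p, qs) if pi > 0)
            dvals.append(min(max(d, 0.0) / log(1 / qmin), 1.0))
        dvals = np.array(dvals)
        species_in = meta.loc[in_season, "species"].values
        # species-level network of mean relative profiles
        profs = []
        sp_names = sorted(set(species_in))
        for sp in sp_names:
            rel = A[species_in == sp]
            rel = rel / rel.sum(axis=1, keepdims=True)
            profs.append(rel.mean(axis=0))
        P = np.array(profs)
        qs2 = P.sum(axis=0) / P.sum()
        qmin2 = min(q for q in qs2 if q > 0)
        for i, sp in enumerate(sp_names):
            p = P[i] / P[i].sum()
            d = sum(pi * log(pi / qi) for pi, qi in zip(p, qs2) if pi > 0)
            out[(sp, se, "species_dprime")] = min(max(d, 0.0) / log(1 / qmin2), 1.0)
        for sp in sp_names:
            mask = species_in == sp
            out[(sp, se, "herd_dprime")] = dvals[mask].mean()
            cell = A[mask]
            out[(sp, se, "herd_richness")] = np.mean([(r > 0).sum() for r in cell])
            # TNW via interpolation/extrapolation formulas written out
            T = len(cell)
            Y = [(cell[:, j] > 0).sum() for j in range(cell.shape[1])]
            Y = [y for y in Y if y > 0]
            S = len(Y)
            q1 = sum(1 for y in Y if y == 1)
            q2 = sum(1 for y in Y if y == 2)
            t = 8
            if t <= T:
                val = S - sum(
                    comb(T - y, t) / comb(T, t) for y in Y if T - y >= t
                )
            else:
                q0 = (
                    (T - 1) / T * q1 * q1 / (2 * q2)
                    if q2 > 0
                    else (T - 1) / T * q1 * (q1 - 1) / 2
                )
                if q1 == 0 or q0 == 0:
                    val = S
                else:
                    val = S + q0 * (1 - (1 - q1 / (q1 + T * q0)) ** (t - T))
            out[(sp, se, "TNW_at_8")] = val
    for sp in sorted(set(meta["species"])):
        su = counts[((meta["species"] == sp) & (meta["season"] == "summer")).values]
        wi = counts[((meta["species"] == sp) & (meta["season"] == "winter")).values]
        bcs = [
            np.abs(a - b).sum() / (a.sum() + b.sum()) for a in su for b in wi
        ]
        out[(sp, "turnover")] = np.mean(bcs)
    return out


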