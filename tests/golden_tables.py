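"""Frozen reference-table values for target PPVs of 99/95/75/50 percent.

Each block: ln(LR+) row key followed by the continuous iteration counts
(2 dp) at prevalences 0.02, 0.05, 0.07, 0.1, 0.15, 0.2.
"""

PREVALENCE_COLUMNS = (0.02, 0.05, 0.07, 0.1, 0.15, 0.2)

_T99 = """\
0.50 16.97 15.08 14.36 13.58 12.66 11.96
1.00 8.49 7.54 7.18 6.79 6.33 5.98
1.50 5.66 5.03 4.79 4.53 4.22 3.99
2.00 4.24 3.77 3.59 3.40 3.16 2.99
2.50 3.39 3.02 2.87 2.72 2.53 2.39
3.00 2.83 2.51 2.39 2.26 2.11 1.99
3.50 2.42 2.15 2.05 1.94 1.81 1.71
4.00 2.12 1.88 1.80 1.70 1.58 1.50
4.50 1.89 1.68 1.60 1.51 1.41 1.33
5.00 1.70 1.51 1.44 1.36 1.27 1.20"""

_T95 = """\
0.50 13.67 11.78 11.06 10.28 9.36 8.66
1.00 6.84 5.89 5.53 5.14 4.68 4.33
1.50 4.56 3.93 3.69 3.43 3.12 2.89
2.00 3.42 2.94 2.77 2.57 2.34 2.17
2.50 2.73 2.36 2.21 2.06 1.87 1.73
3.00 2.28 1.96 1.84 1.71 1.56 1.44
3.50 1.95 1.68 1.58 1.47 1.34 1.24
4.00 1.71 1.47 1.38 1.29 1.17 1.08
4.50 1.52 1.31 1.23 1.14 1.04 0.96
5.00 1.37 1.18 1.11 1.03 0.94 0.87"""

_T75 = """\
0.50 9.98 8.09 7.37 6.59 5.67 4.97
1.00 4.99 4.04 3.69 3.30 2.83 2.48
1.50 3.33 2.70 2.46 2.20 1.89 1.66
2.00 2.50 2.02 1.84 1.65 1.42 1.24
2.50 2.00 1.62 1.47 1.32 1.13 0.99
3.00 1.66 1.35 1.23 1.10 0.94 0.83
3.50 1.43 1.16 1.05 0.94 0.81 0.71
4.00 1.25 1.01 0.92 0.82 0.71 0.62
4.50 1.11 0.90 0.82 0.73 0.63 0.55
5.00 1.00 0.81 0.74 0.66 0.57 0.50"""

_T50 = """\
0.50 7.78 5.89 5.17 4.39 3.47 2.77
1.00 3.89 2.94 2.59 2.20 1.73 1.39
1.50 2.59 1.96 1.72 1.46 1.16 0.92
2.00 1.95 1.47 1.29 1.10 0.87 0.69
2.50 1.56 1.18 1.03 0.88 0.69 0.55
3.00 1.30 0.98 0.86 0.73 0.58 0.46
3.50 1.11 0.84 0.74 0.63 0.50 0.40
4.00 0.97 0.74 0.65 0.55 0.43 0.35
4.50 0.86 0.65 0.57 0.49 0.39 0.31
5.00 0.78 0.59 0.52 0.44 0.35 0.28"""


def _parse(block: str) -> dict[tuple[float, float], float]:
    cells: dict[tuple[float, float], float] = {}
    for line in block.splitlines():
        key, *values = line.split()
        for phi, value in zip(PREVALENCE_COLUMNS, values):
            cells[(float(key), phi)] = float(value)
    return cells


#: target PPV -> {(ln LR+, prevalence): continuous n rounded to 2 dp}
GOLDEN_TABLES: dict[float, dict[tuple[float, float], float]] = {
    0.99: _parse(_T99),
    0.95: _parse(_T95),
    0.75: _parse(_T75),
    0.50: _parse(_T50),
}
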