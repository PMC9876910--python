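"""Published reference values for the standard-model error simulation.

The grid lists, per degree of uncorrected patient rotation (0-30) and
per lateral marker offset (0, 20, 60 mm), the absolute hip-plane factor
error (3 decimals) and the relative error in percent of the reference
factor (1 decimal).  Frozen here as the oracle for the cell-for-cell
reproduction tests.
"""

REFERENCE_FACTOR = 123.45  # hip-plane factor of the standard model, 2 dp

# rotation_deg, abs(i=0), abs(i=20), abs(i=60), rel(i=0), rel(i=20), rel(i=60)
ERROR_GRID_TEXT = """\
0  0.000 0.000 0.000 0.0 0.0 0.0
1  0.002 0.048 0.141 0.0 0.0 0.1
2  0.009 0.101 0.286 0.0 0.1 0.2
3  0.020 0.159 0.435 0.0 0.1 0.4
4  0.036 0.221 0.589 0.0 0.2 0.5
5  0.056 0.287 0.747 0.0 0.2 0.6
6  0.080 0.358 0.909 0.1 0.3 0.7
7  0.109 0.433 1.076 0.1 0.4 0.9
8  0.143 0.514 1.248 0.1 0.4 1.0
9  0.181 0.599 1.424 0.1 0.5 1.2
10 0.224 0.688 1.606 0.2 0.6 1.3
11 0.272 0.783 1.792 0.2 0.6 1.5
12 0.325 0.883 1.983 0.3 0.7 1.6
13 0.382 0.987 2.180 0.3 0.8 1.8
14 0.445 1.097 2.382 0.4 0.9 1.9
15 0.512 1.212 2.589 0.4 1.0 2.1
16 0.585 1.333 2.802 0.5 1.1 2.3
17 0.662 1.459 3.021 0.5 1.2 2.4
18 0.746 1.591 3.246 0.6 1.3 2.6
19 0.834 1.728 3.477 0.7 1.4 2.8
20 0.928 1.871 3.714 0.8 1.5 3.0
21 1.028 2.021 3.958 0.8 1.6 3.2
22 1.134 2.177 4.209 0.9 1.8 3.4
23 1.246 2.339 4.466 1.0 1.9 3.6
24 1.364 2.508 4.731 1.1 2.0 3.8
25 1.489 2.683 5.003 1.2 2.2 4.1
26 1.620 2.866 5.283 1.3 2.3 4.3
27 1.758 3.056 5.571 1.4 2.5 4.5
28 1.903 3.254 5.867 1.5 2.6 4.8
29 2.055 3.459 6.172 1.7 2.8 5.0
30 2.215 3.673 6.486 1.8 3.0 5.3
"""

OFFSETS = (0.0, 20.0, 60.0)

# first rotation reaching an absolute error of 1.5 / 1.0 per offset
THRESHOLD_15 = {0.0: 26, 20.0: 18, 60.0: 10}
THRESHOLD_10_I0 = 21


def parse_grid():
    """-> list of (rotation, {offset: abs_err}, {offset: rel_err})."""
    rows = []
    for line in ERROR_GRID_TEXT.strip().splitlines():
        f = line.split()
        rot = int(f[0])
        abs_err = dict(zip(OFFSETS, map(float, f[1:4])))
        rel_err = dict(zip(OFFSETS, map(float, f[4:7])))
        rows.append((rot, abs_err, rel_err))
    return rows
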