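"""Published thorax-measurement table used as frozen test inputs.

Each row: (pair_id, (ref W1, W2, L), (test W1, W2, L), expected score to
2 decimal places).
"""

MEASUREMENT_TABLE = [
    ("M1", (15.0, 24.8, 14.3), (14.7, 25.3, 14.4), 0.59),
    ("M2", (15.0, 24.8, 14.3), (15.6, 24.9, 14.4), 0.62),
    ("M3", (15.0, 24.8, 14.3), (15.2, 25.2, 14.6), 0.54),
    ("M4", (15.0, 24.8, 14.3), (15.3, 25.0, 14.0), 0.47),
    ("M5", (15.0, 24.8, 14.3), (14.6, 24.9, 13.8), 0.65),
    ("M6", (15.1, 27.2, 16.5), (15.3, 27.0, 15.6), 0.94),
    ("M7", (15.1, 27.2, 16.5), (14.1, 26.7, 16.2), 1.16),
    ("F1", (14.6, 24.9, 13.8), (15.1, 24.1, 13.9), 0.95),
    ("F2", (14.6, 24.9, 13.8), (14.7, 25.3, 14.4), 0.73),
    ("F3", (14.6, 24.9, 13.8), (14.9, 24.0, 13.5), 0.99),
    ("F4", (14.0, 26.1, 16.0), (14.1, 26.7, 16.2), 0.64),
    ("F5", (14.0, 26.1, 16.0), (14.7, 26.0, 16.2), 0.73),
    ("F6", (14.0, 26.1, 16.0), (14.3, 26.9, 15.3), 1.10),
    ("F7", (15.1, 27.2, 16.5), (15.8, 26.8, 16.9), 0.90),
    ("F8", (15.1, 27.2, 16.5), (15.0, 27.2, 15.7), 0.81),
]
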