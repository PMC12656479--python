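"""Published benchmark tables: per-experiment classification accuracies.
These are the printed per-experiment mean +/- SD accuracies (percent) from
an 18-condition subject-independent, multi-session meditation/non-meditation
EEG classification benchmark: 2 meditation tasks (loving-kindness meditation
on self / on others, each vs a non-meditation baseline) x 3 session-pair
counts (3, 4, 5 <=> training sizes 2, 3, 4) x 3 feature pipelines, with 30
experiments per condition.  They serve as *inputs* for printed-value
arithmetic — recomputing the all/bottom-50%/top-50% summary rows and the
pipeline t-tests from the per-experiment rows — not as quantities this
package can regenerate (the underlying real EEG recordings are not shipped).

Keys: (meditation_task, n_session_pairs); pipelines "CSP", "STFT",
"CSP_STFT".  ``PER_EXPERIMENT[key][pipe]`` is a list of 30 (mean, sd)
tuples; ``PRINTED_SUMMARY[key][row][pipe]`` holds the printed summary rows.
"""

from __future__ import annotations

LKM_SELF = "LKM_SELF"
LKM_OTHER = "LKM_OTHER"
PIPELINES = ("CSP", "STFT", "CSP_STFT")

PER_EXPERIMENT = {
    ("LKM_SELF", 3): {
        "CSP": [(66.3, 12.0), (57.7, 15.1), (60.4, 9.2), (61.4, 20.3), (71.7, 9.0), (45.3, 14.8), (51.6, 16.1), (63.6, 21.9), (52.4, 16.0), (50.2, 21.5), (45.8, 15.1), (56.6, 15.5), (53.6, 16.4), (47.8, 15.1), (55.0, 12.2), (63.7, 9.0), (54.3, 25.4), (54.9, 17.9), (63.2, 17.0), (54.2, 14.8), (50.1, 24.1), (69.9, 21.6), (51.6, 10.7), (59.4, 10.7), (58.0, 19.4), (59.4, 18.3), (52.5, 10.2), (47.0, 22.0), (56.1, 14.1), (49.0, 18.3)],
        "STFT": [(59.5, 15.5), (59.1, 10.2), (47.4, 16.6), (79.1, 11.0), (61.0, 14.2), (46.4, 15.3), (72.3, 13.1), (69.2, 11.9), (47.5, 23.2), (64.0, 14.7), (55.0, 11.5), (62.6, 11.7), (53.7, 22.8), (57.9, 16.9), (48.3, 20.9), (50.3, 22.8), (64.0, 19.0), (47.0, 21.1), (65.9, 19.0), (49.5, 19.6), (61.5, 21.0), (58.9, 14.5), (54.8, 21.6), (54.5, 17.1), (57.8, 15.5), (62.5, 17.1), (55.6, 10.6), (54.4, 13.3), (50.9, 20.7), (50.9, 24.1)],
        "CSP_STFT": [(50.6, 25.1), (77.8, 11.3), (72.1, 17.7), (60.1, 19.3), (68.9, 8.6), (77.0, 9.2), (59.0, 20.1), (57.5, 20.0), (54.9, 15.6), (57.9, 14.0), (45.0, 13.8), (68.6, 16.7), (48.2, 22.8), (57.5, 9.6), (74.4, 9.8), (72.0, 15.3), (63.0, 26.8), (80.2, 10.5), (51.2, 21.0), (59.8, 17.7), (65.4, 11.0), (63.3, 14.3), (57.8, 18.4), (44.5, 21.0), (65.2, 13.6), (78.3, 9.7), (51.3, 10.8), (54.5, 19.3), (52.8, 18.8), (79.7, 10.9)],
    },
    ("LKM_OTHER", 3): {
        "CSP": [(67.0, 17.8), (55.1, 23.9), (49.9, 16.0), (49.5, 24.4), (67.0, 14.2), (45.7, 15.7), (63.7, 24.0), (54.7, 11.3), (67.7, 20.5), (50.7, 17.0), (58.3, 10.3), (68.0, 8.8), (55.7, 20.7), (52.5, 16.8), (51.0, 15.9), (56.8, 6.4), (46.6, 19.8), (53.8, 9.2), (52.5, 14.6), (58.1, 15.7), (50.2, 19.5), (65.9, 16.3), (56.9, 16.9), (56.1, 15.7), (63.7, 13.5), (65.1, 16.0), (53.8, 17.2), (62.0, 24.1), (59.8, 9.3), (51.9, 11.8)],
        "STFT": [(46.8, 19.7), (52.7, 23.3), (52.7, 14.4), (50.2, 19.8), (60.0, 12.6), (49.2, 20.4), (51.2, 14.3), (52.6, 19.1), (54.7, 19.7), (57.1, 18.2), (54.3, 17.6), (57.1, 19.1), (56.0, 16.9), (58.3, 19.8), (67.0, 13.3), (50.9, 17.4), (62.2, 16.0), (47.7, 20.7), (56.9, 17.0), (59.7, 14.6), (43.4, 21.5), (60.8, 15.3), (70.8, 8.4), (53.7, 21.9), (61.6, 14.5), (66.7, 10.6), (56.9, 17.6), (47.5, 14.2), (60.6, 18.4), (59.0, 10.7)],
        "CSP_STFT": [(75.1, 10.3), (76.1, 10.3), (52.4, 24.8), (78.9, 17.9), (78.1, 14.8), (78.1, 13.5), (45.2, 24.1), (63.1, 27.2), (66.9, 18.9), (58.2, 12.2), (50.4, 15.8), (51.0, 22.5), (76.4, 8.5), (56.6, 23.1), (53.7, 18.5), (55.9, 15.8), (65.9, 18.6), (60.4, 18.5), (58.5, 15.2), (72.9, 18.9), (64.5, 14.0), (64.1, 20.1), (54.9, 16.3), (53.4, 27.7), (53.3, 15.6), (66.6, 19.6), (62.7, 18.8), (61.0, 17.5), (51.8, 24.5), (63.2, 17.0)],
    },
    ("LKM_SELF", 4): {
        "CSP": [(67.4, 11.4), (57.9, 16.8), (67.2, 19.4), (69.0, 22.2), (62.5, 10.8), (55.9, 18.1), (65.8, 11.9), (61.6, 14.2), (52.0, 15.2), (60.0, 16.9), (62.9, 19.7), (57.9, 15.6), (65.1, 11.7), (54.0, 17.4), (52.0, 15.2), (58.2, 20.3), (49.8, 12.0), (53.2, 17.9), (52.3, 23.1), (52.5, 14.0), (53.2, 17.0), (57.4, 11.9), (64.8, 14.5), (56.2, 15.9), (68.0, 8.6), (56.0, 22.7), (66.0, 8.4), (59.2, 9.2), (67.0, 17.0), (44.5, 19.3)],
        "STFT": [(44.7, 10.4), (52.3, 17.7), (53.4, 19.1), (66.5, 19.6), (65.6, 18.5), (57.5, 16.3), (58.9, 19.0), (69.0, 9.2), (49.7, 18.0), (53.2, 15.0), (52.7, 15.6), (44.8, 11.0), (61.5, 19.9), (62.8, 16.9), (52.4, 18.5), (55.2, 16.9), (56.5, 15.4), (56.7, 12.2), (54.8, 24.3), (66.0, 15.0), (50.2, 22.9), (55.1, 16.1), (67.1, 12.1), (46.0, 13.4), (62.6, 14.2), (62.3, 15.3), (63.0, 14.9), (54.2, 11.5), (75.0, 9.7), (67.0, 10.2)],
        "CSP_STFT": [(62.0, 12.5), (72.1, 19.4), (60.1, 28.0), (71.4, 10.4), (54.3, 21.9), (58.4, 12.1), (54.7, 8.3), (46.4, 18.7), (58.6, 25.5), (57.1, 16.4), (68.8, 13.2), (63.2, 12.9), (63.2, 10.6), (71.2, 20.3), (55.4, 25.0), (47.4, 11.3), (49.6, 17.1), (69.6, 15.1), (55.4, 16.6), (68.7, 12.9), (66.4, 14.3), (62.6, 22.8), (79.1, 8.6), (58.1, 16.2), (70.8, 12.7), (72.8, 7.5), (65.1, 12.6), (73.8, 8.2), (64.0, 19.5), (76.8, 13.0)],
    },
    ("LKM_OTHER", 4): {
        "CSP": [(76.4, 6.8), (43.3, 15.1), (61.4, 25.4), (45.2, 22.5), (75.6, 20.7), (45.6, 17.2), (63.9, 14.5), (68.0, 8.6), (47.8, 14.0), (69.4, 7.2), (57.2, 19.6), (67.4, 18.4), (55.8, 16.7), (49.4, 14.5), (56.4, 18.0), (70.0, 9.7), (41.6, 14.4), (66.7, 7.7), (43.6, 12.6), (48.8, 15.1), (64.6, 16.4), (51.2, 14.3), (70.3, 12.5), (56.8, 13.6), (60.1, 19.1), (68.4, 10.8), (57.5, 10.5), (42.7, 16.6), (63.8, 15.9), (56.1, 12.7)],
        "STFT": [(42.6, 11.1), (72.5, 15.3), (50.3, 15.7), (43.5, 17.2), (48.6, 16.7), (62.9, 24.0), (81.0, 10.2), (78.9, 15.5), (63.9, 19.2), (40.5, 14.7), (54.7, 14.1), (75.5, 14.5), (54.3, 10.8), (53.5, 13.3), (59.7, 17.7), (78.0, 10.4), (54.4, 14.3), (62.3, 12.0), (68.1, 12.4), (64.2, 13.1), (68.8, 20.2), (62.3, 15.8), (54.5, 19.5), (46.9, 14.9), (72.7, 10.7), (66.9, 13.3), (61.9, 13.6), (45.2, 16.7), (59.3, 16.6), (49.8, 14.7)],
        "CSP_STFT": [(75.8, 7.4), (68.9, 25.6), (63.6, 18.9), (63.4, 20.3), (70.8, 10.3), (56.2, 20.8), (55.2, 17.3), (44.8, 15.4), (55.3, 17.8), (53.6, 16.3), (65.2, 19.3), (70.1, 12.3), (60.4, 18.8), (64.2, 15.9), (65.5, 15.7), (51.6, 14.0), (69.2, 8.0), (63.3, 16.6), (70.2, 17.9), (65.5, 11.7), (57.3, 16.0), (57.6, 14.2), (69.3, 13.1), (43.1, 16.3), (52.2, 19.9), (72.4, 10.4), (42.9, 15.9), (60.4, 11.3), (62.9, 16.9), (72.7, 9.5)],
    },
    ("LKM_SELF", 5): {
        "CSP": [(66.1, 12.4), (52.9, 12.1), (63.6, 8.3), (66.5, 17.0), (62.9, 9.1), (60.9, 15.8), (57.4, 16.2), (57.0, 12.5), (61.2, 9.9), (63.4, 18.3), (72.0, 9.4), (61.0, 22.0), (60.7, 16.0), (69.4, 13.3), (58.4, 10.4), (68.1, 20.0), (57.7, 10.8), (38.7, 14.2), (56.0, 15.7), (48.1, 15.7), (56.6, 3.6), (58.8, 4.3), (60.4, 26.3), (63.8, 11.8), (71.9, 12.9), (64.5, 12.7), (50.0, 11.3), (73.6, 14.7), (63.6, 13.8), (66.8, 10.2)],
        "STFT": [(36.5, 12.6), (66.9, 15.0), (66.5, 12.6), (79.8, 14.6), (57.2, 14.2), (63.3, 14.0), (55.0, 9.5), (74.5, 16.1), (61.1, 18.7), (54.4, 16.1), (65.8, 8.6), (66.8, 16.6), (59.3, 12.5), (53.9, 15.5), (52.6, 10.1), (66.2, 18.6), (71.3, 19.4), (56.1, 8.8), (69.8, 6.8), (66.2, 13.1), (45.8, 9.0), (48.0, 9.3), (62.4, 13.9), (50.8, 19.1), (63.4, 11.1), (72.1, 10.0), (50.8, 21.2), (71.9, 9.3), (58.7, 15.2), (57.1, 22.8)],
        "CSP_STFT": [(36.3, 12.2), (52.5, 18.3), (72.0, 8.6), (72.5, 9.8), (73.3, 13.5), (51.2, 14.0), (57.6, 19.1), (74.9, 12.9), (43.4, 22.4), (57.6, 16.8), (42.3, 10.0), (55.6, 15.8), (71.9, 11.2), (74.7, 9.5), (70.3, 17.4), (56.7, 18.3), (75.0, 16.5), (87.5, 8.5), (71.3, 20.4), (49.6, 12.1), (63.2, 7.6), (61.5, 20.0), (43.9, 4.0), (74.0, 15.2), (62.7, 11.0), (59.3, 6.6), (67.9, 10.2), (50.7, 11.8), (62.8, 11.8), (57.4, 7.2)],
    },
    ("LKM_OTHER", 5): {
        "CSP": [(65.7, 14.0), (60.6, 21.3), (71.2, 12.0), (71.8, 18.7), (58.6, 12.6), (55.5, 21.1), (66.9, 6.7), (51.1, 8.4), (56.8, 8.4), (57.5, 19.3), (43.8, 8.9), (57.4, 13.2), (60.9, 13.2), (70.1, 11.7), (53.0, 8.8), (48.7, 14.9), (57.4, 18.4), (41.9, 16.8), (73.2, 10.1), (62.6, 6.6), (52.7, 4.8), (63.7, 13.0), (70.8, 6.0), (63.1, 10.0), (66.4, 16.0), (71.9, 13.9), (49.4, 13.6), (64.1, 6.5), (66.0, 9.3), (66.7, 11.3)],
        "STFT": [(71.7, 7.0), (64.4, 12.0), (54.9, 13.4), (70.7, 15.2), (49.8, 16.7), (56.4, 6.1), (49.7, 16.6), (66.2, 17.7), (67.6, 13.0), (73.5, 11.8), (44.3, 16.0), (69.2, 15.9), (56.4, 22.1), (51.7, 14.4), (56.2, 19.0), (66.0, 16.2), (70.5, 22.6), (67.3, 23.9), (59.7, 9.9), (77.9, 11.5), (69.6, 7.0), (56.2, 7.0), (54.3, 21.2), (53.8, 26.0), (52.2, 24.2), (65.8, 12.2), (54.2, 9.8), (74.8, 9.8), (67.2, 9.1), (65.0, 17.5)],
        "CSP_STFT": [(51.2, 17.8), (61.7, 12.4), (54.2, 17.6), (54.5, 13.9), (51.5, 17.3), (60.9, 11.9), (55.9, 12.2), (64.6, 15.3), (39.5, 7.6), (77.5, 10.8), (65.8, 10.3), (69.7, 9.1), (73.0, 9.1), (74.0, 10.1), (52.4, 13.6), (61.4, 16.7), (58.0, 11.2), (73.9, 9.2), (63.0, 20.0), (29.1, 10.0), (51.6, 13.7), (57.9, 9.4), (71.4, 19.2), (77.1, 7.3), (50.3, 12.6), (71.5, 8.8), (57.4, 17.5), (63.5, 8.6), (67.2, 6.8), (62.2, 7.5)],
    },
}

PRINTED_SUMMARY = {
    ("LKM_SELF", 3): {
        "all": {"CSP": (56.1, 18.0), "STFT": (57.4, 19.1), "CSP_STFT": (62.3, 19.6)},
        "bottom50": {"CSP": (41.7, 12.0), "STFT": (41.7, 11.7), "CSP_STFT": (46.0, 13.2)},
        "top50": {"CSP": (70.4, 9.7), "STFT": (73.1, 9.8), "CSP_STFT": (78.3, 8.7)},
    },
    ("LKM_OTHER", 3): {
        "all": {"CSP": (57.0, 18.0), "STFT": (56.0, 18.4), "CSP_STFT": (62.3, 20.9)},
        "bottom50": {"CSP": (42.7, 11.8), "STFT": (40.8, 11.4), "CSP_STFT": (45.0, 14.1)},
        "top50": {"CSP": (71.3, 10.0), "STFT": (71.1, 9.3), "CSP_STFT": (79.7, 8.5)},
    },
    ("LKM_SELF", 4): {
        "all": {"CSP": (59.0, 17.3), "STFT": (57.9, 17.7), "CSP_STFT": (63.2, 18.4)},
        "bottom50": {"CSP": (45.1, 11.9), "STFT": (43.3, 10.7), "CSP_STFT": (48.7, 13.7)},
        "top50": {"CSP": (72.9, 8.4), "STFT": (72.5, 9.2), "CSP_STFT": (77.7, 8.3)},
    },
    ("LKM_OTHER", 4): {
        "all": {"CSP": (58.2, 18.4), "STFT": (59.9, 18.9), "CSP_STFT": (61.5, 18.2)},
        "bottom50": {"CSP": (43.3, 12.8), "STFT": (44.0, 11.4), "CSP_STFT": (46.8, 13.3)},
        "top50": {"CSP": (73.0, 8.7), "STFT": (75.8, 9.1), "CSP_STFT": (76.1, 7.5)},
    },
    ("LKM_SELF", 5): {
        "all": {"CSP": (61.1, 15.9), "STFT": (60.8, 17.2), "CSP_STFT": (61.6, 18.3)},
        "bottom50": {"CSP": (48.6, 11.8), "STFT": (46.7, 10.5), "CSP_STFT": (46.5, 11.2)},
        "top50": {"CSP": (73.5, 7.7), "STFT": (74.9, 8.9), "CSP_STFT": (76.8, 9.1)},
    },
    ("LKM_OTHER", 5): {
        "all": {"CSP": (60.7, 15.6), "STFT": (61.9, 18.0), "CSP_STFT": (60.7, 16.8)},
        "bottom50": {"CSP": (48.5, 11.3), "STFT": (47.6, 13.2), "CSP_STFT": (47.4, 11.9)},
        "top50": {"CSP": (72.8, 8.0), "STFT": (76.2, 8.3), "CSP_STFT": (74.1, 8.1)},
    },
}


def experiment_means(task: str, n_pairs: int, pipeline: str) -> list[float]:
    """The 30 printed per-experiment mean accuracies for one condition."""
    return [m for m, _ in PER_EXPERIMENT[(task, n_pairs)][pipeline]]


def printed_all_tests_mean(task: str, n_pairs: int, pipeline: str) -> float:
    """The printed "Mean Accuracy (All Tests)" value for one condition."""
    return PRINTED_SUMMARY[(task, n_pairs)]["all"][pipeline][0]


def all_tests_means(pipeline: str) -> list[float]:
    """The six per-condition all-test means for one pipeline (table order)."""
    return [printed_all_tests_mean(t, n, pipeline)
            for (t, n) in PER_EXPERIMENT]
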