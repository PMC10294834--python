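variable,G_brevicaudus,G_ussuriensis,G_saxatilis,median_reported
tpi,76.25,184.75,10.90,76.25
slope,53.17,115.58,7.30,53.17
temperature,48.12,116.11,10.46,48.12
precipitation,43.93,88.76,6.04,43.93
forest,43.80,87.36,4.39,43.80
herbaceous,44.75,76.49,3.94,44.75
bare,11.96,24.51,1.09,11.96
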