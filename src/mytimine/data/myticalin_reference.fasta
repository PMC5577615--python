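>A3 myticalin A3 predicted mature peptide, C-terminally amidated
YGWPRMPRIPRKPRYPRYPRYPRWPRHPTIYA-NH2
>A4 myticalin A4 predicted mature peptide, C-terminally amidated
YSWPRMPRIPRLPRYPRYPRYPRYPRWPRHPTIYA-NH2
>A5 myticalin A5 predicted mature peptide, C-terminally amidated
YSWPRMPRIPRLPRYPRYPRYPRWPRWPRQPTIYA-NH2
>C10 myticalin C10 predicted mature peptide, free acid
GRRRRYRYWRRGYRSWRRGVTIQERSKSSTLNTED
>C-PG myticalin C pseudogene virtual peptide (in-frame stop)
RRRRRYRYWRRGLTI*GRSKSLPLNTGD
>D-PG1 myticalin D pseudogene 1 virtual peptide (two in-frame stops)
WGRRWRV*IPSPPRIRPWPP*TWPRPKWPRSATINID
>D-PG2 myticalin D pseudogene 2 virtual peptide (exon 2 partially deleted)
WGRRLRIRIPSPPRPRPWPRPYPGPWPRSATINTDQ
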