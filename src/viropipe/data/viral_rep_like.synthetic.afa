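>viral_rep_like_consensus
MNKVDLNLSRIDRYVSAENAQIAEFALPCEVQEFATKFQVWGFLKHTCSGGQPAGDNKYNIQSVIYTYRE
QTKVSNNYFDCGELVKVALQPTYPSTMPEITRLVQGYRMR
>viral_rep_like_seed1
MHKVWLNLSRIDRYVSAENAQIAEFALPCEVQEFATKFQAWGFLCHTCSGGQPAGDNKYNIQSVIYTYRE
QTKVSNNYFDCGELVKVALQPTYPSTMPPITRLVQGWRMR
>viral_rep_like_seed2
MHKVDLVLSRIDRYVSAENAQIAEFALPCEVQEFATKFPVWGFLKHTCSAGQQAGDNKFNIQSVIYTYRE
QTKVSNNYFDCGELVKVALQPTYPSTMPEITRLVQGYRMR
>viral_rep_like_seed3
MNKVDLNLSRIDRYVSAENAQIAEFAQPCEVQEFATKFQVWGFLKHTCSSGQPARDNKYNIQSVIYTARE
QGKHSNNYFDCGELVKVALQPTYPSTMPEITRLVQGYRMR
>viral_rep_like_seed4
MNKVDLKLSRIDRYVSAENAQIAEFALPCEVQEFATKFQVWLFLKHTCSGAQPAGDNKYNIQSVIYTYRE
QTKVSNNYFDCGELVKVALQPTYPRTMPEITRMVQKYRMR
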