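>phage_f_like_consensus
MDRRLYAHGDKQMENGDLILAPQALEQQAGGPHTTAISKFRMDHSITIILDEKVPLPAPIDKLEWGDQMY
SSGASSYFEMVGKLMHYAYVKGGSASPKPARNYCLNASVAVFPRSLHHITKTAFGLITVYLEMDGGFCWV
DGRPHRSKETGPYQTLQMQTKHVANAGDYNLKQDKADPDVQEFNYQKGTVVLEEVEGWKVRLDPENEEYS
ISIKPGWPAAVFKLAQIGVARGKAEQGLPSMFMVVVGKGKGAVSMNGFDSPQGEVETGKTQLLKYYHGAH
RQLELDPAMKDETGYSWKIRVMINAQEEILFIVKEPIYPITGLEYCTKGRGFGYAGMQLKWYKGDLLGGA
LKSKARGINQLATKTTWGGGKWENIPKYKQAFAEPAKLKAIDGVRALGGFLAKKSAIMAFVAEFALRNII
>phage_f_like_seed1
MDRRLYAHGDKQMENGDLILAPNALEQQAGGPHTTAISKFRMDHSITIILDETVPLPAPIDKLEWGDQMY
SLGASSMFEMVNKLMHDAYVKGGSASPKRARNYCLNASVAVFPRSLHHITKTAFGLITVYLESDGGFCWV
DGRPHRSKETGPYQTLQMQTKHVANAGDYNLKQDKADPDVQEFNYQKGTVVLEEVEGWKWRLDPENEEYS
ISIKPGWPAAVFKLAQIGVARGRAEQGLPSMFMVVVGKGKGAVSMNGFDSPQGEVETGKTQLLKYYHGAH
RQLELDPAMKDETGLSWKIRVMINAQELILRIVKEPIYPITGLEYCTRGRGFGYVGMQLKWYKPDLLGGA
LKSKARSINQLATKTTWGGGKWENIPKYDQADAEPAPLKAIDGVRALGGFLAPKSAIMAFVAEFALRNII
>phage_f_like_seed2
MDRRLYAHGDKQMENGDLILAPQALEQQAGGPHTTAISKFRMDHRITYILDEKVPLPAPIDKLEWGDQMY
SSGASSYFEMVGKLMHYAYVKGGSAGPKPARNYCLNASVAVRPRSLHHITKNAFGLITVYLEMDGGFCWV
DGRPHRSKETGPYQTLQMQTKHVANAGDYNLKQQKADPDVQEFFYQKGTVHLEEVEAWKVRLDPENEEYS
ISIKPGLPAAVFKLAQIGVARGKAEQGLPSMFMVVVGKGKGAVSMNGFDSPQGEVETGKTQLLKYYHGAH
RQLELDPAMKDETGYSWKIRVMINAQEEILFIVKEPIYPQTGLEYCTKQRGFGYAGSQLKWYKGDLLFGA
LKDFARGINQLATKTTWGGGKWECIPKYKQAFAEPAKLKAIDILRALGGFDAKKSAIMAFVAEYALRNII
>phage_f_like_seed3
MDRRLLAHGDKQMENGDLILAPQALEQQAGGPHNTAISKFRMDHSINIILDEKVPLPAPIDKLEWGDYMY
SSGALSYFEMVGKLMWYAYVKGGSAQPKPARNYCLNASVAVFPRSLHHIDKTAFGLITVYLEMDGGFCWV
DGRPHRSKQTGPYQTLQMQTKHVANAGDYNLKQDKADPDVQEFNYQKGTVVLEEVEGWKVRLDGENEEYS
ISIKPGWPAAVFKLAQIGVARGKAEQSLPSMFMVVVGKGKGAVSMNGFDSPQGEVETRKTQLLKYYHGAH
RQLELDPANNDETGYSWKIRDMINAQHDIHFIVKEPIFPITGSEYCTKGRGFGYAGMQLKWYKGDLLGGA
LKSKARGINQLATKTTWGGGKWENIPKYKQAFAEPAKLKWIDGVRALGGFLAKKSAIMAFVAEFALRNII
>phage_f_like_seed4
MTRRLYAHGCTQMENGDLILHPQALEQQAGGPHTTAISKFRMDNSGTIILDEKVPLPAPIDKLEWGDQMY
SSGASSYFEFVGKLMHYAYVKGGSASPKPARNYCLNASVATFPRSLHHICKTAFGLITVYLEMDGGFCWV
DGRPHWSGETGPYQTLQMQTKHVANAGDYNLFQDKATPDVQEFNYQKGTVVLEEVEGWKVRLDPENEEMS
ISIKPGWPAAVFKLAQIGVARGEAEQGLPSMFMVVVGKGKGAVSMNGFDSPQGEVETGKTQLLDYYHGAH
RQLELDPAMKDETGYSEKIRVMINAQEEILQIVKEPIYPITGLEYCTKGRGFGYAGMQLKWYKGDLLGGA
LKSKARGINQLATKTTDGGGKWENIRKYKQAFAEPAKLKAIDGVRALGGFLAKKQAIMAFVAEFALRNII
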