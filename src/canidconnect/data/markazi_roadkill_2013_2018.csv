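species,season,year,count
golden_jackal,Spring,2013,20
golden_jackal,Spring,2014,13
golden_jackal,Spring,2015,5
golden_jackal,Spring,2016,10
golden_jackal,Spring,2017,7
golden_jackal,Spring,2018,8
golden_jackal,Summer,2013,10
golden_jackal,Summer,2014,10
golden_jackal,Summer,2015,4
golden_jackal,Summer,2016,3
golden_jackal,Summer,2017,7
golden_jackal,Summer,2018,7
golden_jackal,Autumn,2013,8
golden_jackal,Autumn,2014,9
golden_jackal,Autumn,2015,1
golden_jackal,Autumn,2016,2
golden_jackal,Autumn,2017,0
golden_jackal,Autumn,2018,3
golden_jackal,Winter,2013,13
golden_jackal,Winter,2014,15
golden_jackal,Winter,2015,3
golden_jackal,Winter,2016,9
golden_jackal,Winter,2017,1
golden_jackal,Winter,2018,5
grey_wolf,Spring,2013,4
grey_wolf,Spring,2014,4
grey_wolf,Spring,2015,5
grey_wolf,Spring,2016,1
grey_wolf,Spring,2017,3
grey_wolf,Spring,2018,5
grey_wolf,Summer,2013,4
grey_wolf,Summer,2014,3
grey_wolf,Summer,2015,4
grey_wolf,Summer,2016,10
grey_wolf,Summer,2017,4
grey_wolf,Summer,2018,2
grey_wolf,Autumn,2013,5
grey_wolf,Autumn,2014,2
grey_wolf,Autumn,2015,2
grey_wolf,Autumn,2016,3
grey_wolf,Autumn,2017,5
grey_wolf,Autumn,2018,2
grey_wolf,Winter,2013,9
grey_wolf,Winter,2014,6
grey_wolf,Winter,2015,8
grey_wolf,Winter,2016,5
grey_wolf,Winter,2017,5
grey_wolf,Winter,2018,2
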